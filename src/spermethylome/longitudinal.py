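"""Within-subject longitudinal change detection and dynamic-CpG enrichment.

Each follow-up sample is compared to the same subject's own baseline
(timepoint 0): a CpG is called altered when |delta beta| strictly exceeds
the cutoff (0.2 by default, ~20 percentage points of methylation). Control
(CC) subjects define the expected technical/biological drift — the mean
altered count over their 6/12/18-month follow-ups — against which treated
subjects' counts are expressed as fold changes. Venn-style intersections
across a subject's follow-ups identify acute (6-month-only) versus
persistent alterations, and intersections across subjects identify shared
sites.

In capture (sequencing) mode, where no baseline exists, consecutive
follow-ups are compared instead, CpGs must reach the minimum coverage in
every sample, and altered sites are classified against the dynamic-CpG band
(intermediate 20-80% reference methylation) with a Yates-corrected
chi-squared comparing alteration loads between subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .io import BetaMatrix, SampleManifest

__all__ = [
    "DeltaCounts",
    "delta_counts",
    "reference_drift",
    "fold_vs_reference",
    "intersect_timepoints",
    "common_across_subjects",
    "filter_common_covered",
    "classify_dynamic",
    "dynamic_fraction_of_changes",
    "yates_chisq",
    "LongitudinalModel",
    "LongitudinalResults",
]


@dataclass
class DeltaCounts:
    n_hypo: int
    n_hyper: int
    altered: frozenset

    @property
    def n_total(self) -> int:
        return self.n_hypo + self.n_hyper


def delta_counts(
    baseline: pd.Series, followup: pd.Series, cutoff: float = 0.2
) -> DeltaCounts:
    """Count CpGs whose beta changed by strictly more than ``cutoff``.

    delta = followup - baseline; hypermethylated when delta > cutoff,
    hypomethylated when delta < -cutoff (both strict — a change of exactly
    the cutoff is not counted). CpGs missing in either sample are excluded.
    """
    common = baseline.index.intersection(followup.index)
    if len(common) == 0:
        raise ValueError("baseline and follow-up share no probes")
    delta = followup.reindex(common) - baseline.reindex(common)
    delta = delta.dropna()
    hyper = delta.index[delta > cutoff]
    hypo = delta.index[delta < -cutoff]
    return DeltaCounts(len(hypo), len(hyper), frozenset(hypo) | frozenset(hyper))


def reference_drift(report: pd.DataFrame, months: Sequence[float] = (6.0, 12.0, 18.0)) -> float:
    """Mean altered-site count over control follow-ups.

    ``report`` is a per-(subject, follow-up) table with cohort, the
    follow-up timepoint and n_total; the reference is the mean n_total over
    CC rows at the given months.
    """
    cc = report[(report["cohort"] == "CC") & report["timepoint_months"].isin(months)]
    if cc.empty:
        raise ValueError("no CC follow-ups at the reference months")
    return float(cc["n_total"].mean())


def fold_vs_reference(n_total: int, reference_mean: float) -> float:
    """Altered-count ratio against the control drift expectation."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return n_total / reference_mean


def intersect_timepoints(sets: Mapping) -> tuple[dict, frozenset]:
    """Exact Venn cell counts over a subject's altered-site sets.

    ``sets`` maps a timepoint label to its altered-site set. Returns
    (cells, persistent): ``cells`` maps each non-empty membership pattern
    (a tuple of labels, sorted) to the number of sites belonging to exactly
    those sets; ``persistent`` is the intersection of all sets. Cell counts
    partition the union.
    """
    labels = list(sets)
    if len(labels) < 2:
        raise ValueError("need >= 2 sets")
    membership: dict = {}
    for lab in labels:
        for site in sets[lab]:
            membership.setdefault(site, set()).add(lab)
    cells: dict[tuple, int] = {}
    for site, labs in membership.items():
        key = tuple(sorted(labs, key=labels.index))
        cells[key] = cells.get(key, 0) + 1
    persistent = frozenset.intersection(*(frozenset(sets[l]) for l in labels))
    return cells, persistent


def common_across_subjects(sets: Mapping) -> tuple[frozenset, dict]:
    """Sites altered in every subject, plus per-subject shared fractions."""
    if len(sets) < 2:
        raise ValueError("need >= 2 subjects")
    shared = frozenset.intersection(*(frozenset(v) for v in sets.values()))
    fractions = {
        k: (len(shared) / len(v) if len(v) else float("nan")) for k, v in sets.items()
    }
    return shared, fractions


def filter_common_covered(
    betas: BetaMatrix, min_coverage: int = 10, exclusive: bool = False
) -> BetaMatrix:
    """Restrict to CpGs reaching ``min_coverage`` in *every* sample.

    The threshold is inclusive (>=) by default; ``exclusive=True`` uses a
    strict >. Requires the coverage companion matrix.
    """
    if betas.coverage is None:
        raise ValueError("no coverage matrix present")
    cov = betas.coverage.to_numpy()
    ok = (cov > min_coverage).all(axis=1) if exclusive else (cov >= min_coverage).all(axis=1)
    if not ok.any():
        import warnings

        warnings.warn("no CpGs pass the common-coverage filter", stacklevel=2)
    keep = betas.beta.index[ok]
    return betas.select_probes(list(keep))


def classify_dynamic(
    reference_means: pd.Series, low: float = 0.2, high: float = 0.8
) -> pd.DataFrame:
    """Dynamic/static classification from reference mean methylation.

    A CpG is *dynamic* when its reference mean beta lies in [low, high]
    (inclusive bounds — "20-80% methylated"); otherwise static.
    """
    dyn = (reference_means >= low) & (reference_means <= high)
    return pd.DataFrame(
        {"reference_mean_beta": reference_means, "dynamic": dyn}
    )


def dynamic_fraction_of_changes(
    altered: Iterable, classification: pd.DataFrame
) -> float | None:
    """Percent of altered CpGs falling at dynamic sites (None if no sites)."""
    altered = list(altered)
    if not altered:
        return None
    missing = [a for a in altered if a not in classification.index]
    if missing:
        raise ValueError(f"{len(missing)} altered sites lack a classification")
    dyn = classification.loc[altered, "dynamic"]
    return 100.0 * float(dyn.sum()) / len(altered)


def yates_chisq(altered_a: int, n_a: int, altered_b: int, n_b: int) -> tuple[float, float]:
    """Yates-continuity-corrected chi-squared on alteration proportions.

    Builds the 2x2 table (altered / unaltered per group) and computes
    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / [(a+b)(c+d)(a+c)(b+d)],
    with a two-sided p from the 1-df chi-squared distribution.
    """
    a, b = altered_a, n_a - altered_a
    c, d = altered_b, n_b - altered_b
    if min(a, b, c, d) < 0:
        raise ValueError("altered counts exceed totals or are negative")
    N = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if min(margins) == 0:
        raise ValueError("chi-squared undefined: a table margin is zero")
    num = max(abs(a * d - b * c) - N / 2.0, 0.0)
    chi2 = N * num**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


class LongitudinalModel:
    """Within-subject longitudinal change model.

    Array mode compares every follow-up to the subject's own baseline
    (timepoint 0); subjects without a baseline are skipped and reported.
    Capture mode compares consecutive follow-ups, after restricting to CpGs
    covered at ``min_coverage`` in every sample.
    """

    def __init__(
        self,
        betas: BetaMatrix,
        manifest: SampleManifest,
        config: AnalysisConfig | None = None,
        mode: str = "array",
    ):
        if mode not in ("array", "capture"):
            raise ValueError("mode must be 'array' or 'capture'")
        self.config = config or AnalysisConfig()
        self.mode = mode
        if mode == "capture":
            betas = filter_common_covered(
                betas, self.config.min_coverage, self.config.coverage_exclusive
            )
        self.betas = betas
        self.manifest = manifest

    def fit(self) -> "LongitudinalResults":
        cfg = self.config
        mf = self.manifest.frame
        beta = self.betas.beta
        rows = []
        altered_sets: dict[tuple[str, float], frozenset] = {}
        skipped: list[str] = []
        for subj in dict.fromkeys(mf["subject_id"]):
            sub = mf[mf["subject_id"] == subj].sort_values("timepoint_months")
            sub = sub[sub["sample_id"].isin(beta.columns)]
            if len(sub) < 2:
                skipped.append(subj)
                continue
            cohort = sub["cohort"].iloc[0]
            tps = sub["timepoint_months"].to_numpy()
            sids = sub["sample_id"].to_numpy()
            if self.mode == "array":
                if tps[0] != 0:
                    skipped.append(subj)
                    continue
                pairs = [((sids[0], tps[0]), (sids[i], tps[i])) for i in range(1, len(sids))]
            else:
                pairs = [
                    ((sids[i], tps[i]), (sids[i + 1], tps[i + 1]))
                    for i in range(len(sids) - 1)
                ]
            for (sid0, t0), (sid1, t1) in pairs:
                dc = delta_counts(beta[sid0], beta[sid1], cfg.delta_beta_cutoff)
                altered_sets[(subj, float(t1))] = dc.altered
                rows.append(
                    {
                        "subject_id": subj,
                        "cohort": cohort,
                        "baseline_months": float(t0),
                        "timepoint_months": float(t1),
                        "n_hypo": dc.n_hypo,
                        "n_hyper": dc.n_hyper,
                        "n_total": dc.n_total,
                    }
                )
        report = pd.DataFrame(rows)
        ref = float("nan")
        if not report.empty:
            months = (6.0, 12.0, 18.0) if self.mode == "array" else tuple(report["timepoint_months"].unique())
            try:
                ref = reference_drift(report, months=months)
            except ValueError:
                ref = float("nan")
            if np.isfinite(ref) and ref > 0:
                report["fold_vs_reference"] = report["n_total"] / ref
            else:
                report["fold_vs_reference"] = np.nan
        reference_means = beta.mean(axis=1, skipna=True)
        classification = classify_dynamic(reference_means, cfg.dynamic_low, cfg.dynamic_high)
        return LongitudinalResults(
            table=report,
            reference_mean=ref,
            altered_sets=altered_sets,
            classification=classification,
            n_probes=len(beta.index),
            mode=self.mode,
            skipped_subjects=skipped,
        )


@dataclass
class LongitudinalResults:
    """Per-subject follow-up alteration counts and derived intersections."""

    table: pd.DataFrame
    reference_mean: float  # CC drift: mean altered count per follow-up
    altered_sets: dict
    classification: pd.DataFrame
    n_probes: int
    mode: str
    skipped_subjects: list = field(default_factory=list)

    def subject_sets(self, subject_id: str) -> dict:
        return {
            tp: s for (subj, tp), s in self.altered_sets.items() if subj == subject_id
        }

    def venn(self, subject_id: str) -> tuple[dict, frozenset]:
        """Venn cells + persistent sites across a subject's follow-ups."""
        return intersect_timepoints(self.subject_sets(subject_id))

    def common_sites(self, subject_ids: Sequence[str], timepoint: float) -> tuple[frozenset, dict]:
        sets = {s: self.altered_sets[(s, float(timepoint))] for s in subject_ids}
        return common_across_subjects(sets)

    def dynamic_fractions(self) -> pd.Series:
        """Percent of altered sites at dynamic CpGs, per subject x follow-up."""
        out = {}
        for key, altered in self.altered_sets.items():
            frac = dynamic_fraction_of_changes(altered, self.classification)
            out[key] = np.nan if frac is None else frac
        return pd.Series(out, dtype=float)

    def alteration_test(self, subject_a: str, subject_b: str) -> tuple[float, float]:
        """Yates chi-squared comparing two subjects' total alteration loads."""
        ta = int(self.table.loc[self.table["subject_id"] == subject_a, "n_total"].sum())
        tb = int(self.table.loc[self.table["subject_id"] == subject_b, "n_total"].sum())
        na = self.n_probes * int((self.table["subject_id"] == subject_a).sum())
        nb = self.n_probes * int((self.table["subject_id"] == subject_b).sum())
        return yates_chisq(ta, na, tb, nb)

    def summary(self) -> str:
        lines = [f"Longitudinal alteration report ({self.mode} mode)", "=" * 50]
        lines.append(f"probe universe: {self.n_probes}")
        if np.isfinite(self.reference_mean):
            lines.append(f"CC reference drift: {self.reference_mean:.1f} altered sites per follow-up")
        if self.skipped_subjects:
            lines.append(f"skipped (no usable baseline/pairs): {self.skipped_subjects}")
        if not self.table.empty:
            cols = ["subject_id", "cohort", "timepoint_months", "n_hypo", "n_hyper", "n_total", "fold_vs_reference"]
            lines.append(self.table[cols].to_string(index=False, float_format=lambda x: f"{x:.2f}"))
        return "\n".join(lines)
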