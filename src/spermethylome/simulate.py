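"""Synthetic longitudinal sperm-methylome cohorts with ground truth.

The generator reproduces the statistical structure the downstream analyses
assume, so that every stage is exercisable without external data:

* a bimodal per-probe baseline profile — most CpGs near 0 or 1 ("static"),
  a minority at intermediate methylation ("dynamic", higher variance);
* imprinting control regions (ICRs): paternally methylated ICR probes near
  full methylation, maternally methylated ones near zero;
* cohort-specific implanted signatures, e.g. hypomethylation of a GDF2-like
  promoter in the testicular-cancer (TC) cohort and hypermethylation of a
  SPON2-like region in the Hodgkin-disease (HD) cohort, present at every
  timepoint (disease signatures, not treatment effects);
* a transient treatment pulse at the 6-month follow-up in treated cohorts,
  decaying geometrically afterwards, with optional per-subject persistence;
* within-subject technical/biological noise plus extra longitudinal drift at
  follow-ups; all betas clipped to [0, 1];
* optional somatic-cell contamination of chosen samples (two-component
  mixture pulling ICRs toward the somatic expectation);
* capture mode: a denser CpG universe with per-CpG negative-binomial
  coverage so the minimum-coverage filter has something to chew on.

Noise standard deviations are calibration constants, not measured values:
the array-mode dynamic SD is solved so the expected number of |delta beta| >
0.2 events per control follow-up across the default 385,553-probe universe
is ~145; capture-mode SDs are solved so ~2.3% of covered CpGs change between
follow-ups with ~83% of changes at dynamic CpGs. See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix, ProbeAnnotation, RegionSet, SampleManifest

__all__ = [
    "Signature",
    "TreatmentPulse",
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedCohort",
    "default_regions",
    "default_signatures",
    "simulate_cohort",
    "add_contamination",
    "somatic_profile",
]

# rounded hg19 autosome lengths (bp), used to spread probes over a genome
_CHROM_LENGTHS = {
    "chr1": 249_000_000, "chr2": 243_000_000, "chr3": 198_000_000,
    "chr4": 191_000_000, "chr5": 181_000_000, "chr6": 171_000_000,
    "chr7": 159_000_000, "chr8": 146_000_000, "chr9": 141_000_000,
    "chr10": 136_000_000, "chr11": 135_000_000, "chr12": 134_000_000,
    "chr13": 115_000_000, "chr14": 107_000_000, "chr15": 103_000_000,
    "chr16": 90_000_000, "chr17": 81_000_000, "chr18": 78_000_000,
    "chr19": 59_000_000, "chr20": 63_000_000, "chr21": 48_000_000,
    "chr22": 51_000_000,
}


@dataclass(frozen=True)
class Signature:
    """A cohort-specific methylation signature implanted at baseline.

    Either pinned to a named region (``region`` set: every probe of that
    region receives the cohort effects) or dispersed (``n_sites`` probes
    drawn from the dynamic-CpG pool; per-probe sign drawn with probability
    ``hypo_prob`` of hypomethylation, magnitude ``magnitude``).
    """

    name: str
    effects: Mapping[str, float] = field(default_factory=dict)  # cohort -> delta
    region: str | None = None
    cohort: str | None = None  # dispersed signatures target one cohort
    n_sites: int = 0
    magnitude: float = 0.15
    hypo_prob: float = 0.65


@dataclass(frozen=True)
class TreatmentPulse:
    """Acute post-chemotherapy perturbation applied to treated cohorts.

    ``n_sites`` CpGs per subject, drawn from a shared pool of size
    ``n_sites / pool_overlap`` (so two treated subjects share ~``pool_overlap``
    of their affected sites), are shifted by ``magnitude`` (sign toward the
    beta midpoint) at ``onset_month``; the shift decays geometrically by
    ``decay`` per subsequent timepoint. Subjects listed in
    ``persister_subjects`` keep the full-magnitude pulse at all follow-ups,
    emulating the rare patient with alterations persisting to 2 years.
    """

    magnitude: float = 0.3
    n_sites: int = 2900
    decay: float = 0.25
    pool_overlap: float = 0.25
    onset_month: float = 6.0
    persister_subjects: tuple[str, ...] = ("HD1",)


def default_regions() -> RegionSet:
    """ICRs plus candidate signature loci, at synthetic coordinates.

    Sperm/somatic beta expectations: paternally methylated ICRs ~0.93 in
    sperm, maternally methylated ~0.02; both ~0.5 in somatic tissue (one
    methylated allele).
    """
    rows = [
        ("chr11", 2_019_000, 2_019_800, "H19_ICR", "paternal", 0.93, 0.50),
        ("chr7", 130_130_000, 130_130_800, "MEST_ICR", "maternal", 0.02, 0.50),
        ("chr11", 2_720_000, 2_720_800, "KCNQ1OT1_ICR", "maternal", 0.02, 0.50),
        ("chr15", 25_200_000, 25_200_800, "SNRPN_ICR", "maternal", 0.02, 0.50),
        ("chr10", 48_410_000, 48_412_200, "GDF2_promoter", "none", np.nan, np.nan),
        ("chr4", 1_160_000, 1_161_050, "SPON2_region", "none", np.nan, np.nan),
        ("chr13", 45_000_000, 45_000_900, "BASP1P1_region", "none", np.nan, np.nan),
    ]
    return RegionSet(
        pd.DataFrame(
            rows,
            columns=[
                "chrom", "start", "end", "name",
                "parent_of_origin", "expected_sperm_beta", "expected_somatic_beta",
            ],
        )
    )


def default_signatures() -> tuple[Signature, ...]:
    """Built-in baseline disease signatures.

    The GDF2-like promoter loses 20 percentage points of methylation in TC;
    the SPON2-like region gains methylation in HD and loses some in TC (HD
    highest, TC lowest); a BASP1P1-like locus is hypomethylated in both
    cancer cohorts; and each cancer cohort additionally carries 250 dispersed
    differentially methylated CpGs (hypo-biased), which is what the top-500
    clustering signature recovers.
    """
    return (
        Signature("gdf2_tc_hypo", effects={"TC": -0.20}, region="GDF2_promoter"),
        Signature("spon2_hd_hyper", effects={"HD": 0.15, "TC": -0.10}, region="SPON2_region"),
        Signature("basp1p1_hypo", effects={"HD": -0.15, "TC": -0.15}, region="BASP1P1_region"),
        Signature("hd_dispersed", cohort="HD", n_sites=250, magnitude=0.15, hypo_prob=0.65),
        Signature("tc_dispersed", cohort="TC", n_sites=250, magnitude=0.15, hypo_prob=0.65),
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the array-mode study design: 7 CC / 7 HD / 6 TC subjects,
    385,553 retained probes, collections at baseline and 6-month intervals
    to 24 months. ``SimulationConfig.capture()`` gives the sequencing-like
    design (4 subjects, two follow-ups, per-CpG coverage).
    """

    n_cc: int = 7
    n_hd: int = 7
    n_tc: int = 6
    n_probes: int = 385_553
    timepoints_months: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0)
    mode: str = "array"  # "array" | "capture"
    #: fraction of non-region probes given an intermediate (dynamic) profile
    dynamic_fraction: float = 0.14
    #: per-cell noise SD for static probes (beta scale)
    static_noise_sd: float = 0.01
    #: per-cell noise SD for dynamic probes
    dynamic_noise_sd: float = 0.046
    #: extra per-cell SD applied at follow-up timepoints only
    longitudinal_drift_sd: float = 0.015
    #: static baseline profiles are drawn uniform on these two bands
    static_low_band: tuple[float, float] = (0.03, 0.17)
    static_high_band: tuple[float, float] = (0.83, 0.97)
    #: dynamic profiles are drawn uniform on this band
    dynamic_band: tuple[float, float] = (0.2, 0.8)
    regions: RegionSet | None = None
    signatures: tuple[Signature, ...] | None = None
    pulse: TreatmentPulse | None = None
    #: sample_id -> somatic fraction mixed into that sample
    contamination: Mapping[str, float] = field(default_factory=dict)
    probes_per_icr: int = 8
    multi_mapped_rate: float = 0.01
    snp_probe_rate: float = 0.02
    #: capture mode: negative-binomial coverage (mean, dispersion k)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    #: capture mode: extra altered dynamic CpGs per treated subject between
    #: follow-ups (the elevated alteration load of cancer patients), as a
    #: fraction of the CpG universe so reduced universes stay faithful
    treated_extra_dynamic_fraction: float = 0.0076
    treated_extra_magnitude: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cc, self.n_hd, self.n_tc) < 0 or self.n_cc + self.n_hd + self.n_tc < 1:
            raise ValueError("cohort sizes must be non-negative, at least one subject")
        for name in ("static_noise_sd", "dynamic_noise_sd", "longitudinal_drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dynamic_fraction <= 1:
            raise ValueError("dynamic_fraction must be in [0, 1]")
        if self.mode not in ("array", "capture"):
            raise ValueError("mode must be 'array' or 'capture'")
        self.timepoints_months = tuple(float(t) for t in self.timepoints_months)
        # YAML-friendly construction: plain dicts for nested specs
        if isinstance(self.pulse, dict):
            self.pulse = TreatmentPulse(**self.pulse)
        if self.signatures is not None:
            self.signatures = tuple(
                Signature(**s) if isinstance(s, dict) else s for s in self.signatures
            )
        if self.regions is None:
            self.regions = default_regions()
        if self.signatures is None:
            self.signatures = default_signatures()
        if self.pulse is None and self.mode == "array":
            self.pulse = TreatmentPulse()

    @classmethod
    def capture(cls, **overrides) -> "SimulationConfig":
        """Sequencing-like design: dense universe, coverage, two follow-ups.

        Noise SDs are recalibrated for the coverage-limited assay (larger
        per-measurement error); there is no baseline, so follow-ups are
        compared consecutively downstream and no drift term is added.
        """
        defaults = dict(
            n_cc=2, n_hd=1, n_tc=1,
            n_probes=1_711_875,
            timepoints_months=(12.0, 18.0),
            mode="capture",
            dynamic_fraction=0.25,
            static_noise_sd=0.054,
            dynamic_noise_sd=0.08,
            longitudinal_drift_sd=0.0,
            pulse=None,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort (the acceptance surface)."""

    baseline_profile: pd.Series  # per-probe population beta
    dynamic: pd.Series  # bool per probe: intermediate-methylation profile
    signature_sites: pd.DataFrame  # signature, probe_id, cohort, effect
    pulse_sites: dict[str, np.ndarray]  # subject -> probe ids
    pulse_magnitude: dict[tuple[str, float], float]  # (subject, month) -> shift
    capture_extra_sites: dict[str, np.ndarray]
    contamination: dict[str, float]  # sample_id -> alpha

    def signature_site_count(self, cohort: str) -> int:
        df = self.signature_sites
        return int((df["cohort"] == cohort).sum())


@dataclass
class SimulatedCohort:
    betas: BetaMatrix
    manifest: SampleManifest
    annotation: ProbeAnnotation
    regions: RegionSet
    truth: SyntheticTruth

    def __iter__(self):
        # allow `betas, manifest, annotation, truth = simulate_cohort(cfg)`
        return iter((self.betas, self.manifest, self.annotation, self.truth))


def _build_annotation(cfg: SimulationConfig, rng: np.random.Generator):
    """Probe universe: region-pinned probes plus genome-scattered probes."""
    regions = cfg.regions.frame
    special_rows: list[tuple[str, str, int]] = []
    region_probes: dict[str, list[str]] = {}
    n_per_region = {
        "GDF2_promoter": 21,
        "SPON2_region": 20,
        "BASP1P1_region": 8,
    }
    for _, r in regions.iterrows():
        n = n_per_region.get(r["name"], cfg.probes_per_icr)
        span = int(r["end"] - r["start"])
        step = max(span // (n + 1), 1)
        ids = []
        for i in range(n):
            pos = int(r["start"]) + step * (i + 1)
            pid = f"{r['name']}_p{i:02d}"
            special_rows.append((pid, r["chrom"], pos))
            ids.append(pid)
        region_probes[r["name"]] = ids
    n_special = len(special_rows)
    if n_special > cfg.n_probes:
        raise ValueError("n_probes smaller than the built-in region probe count")
    n_random = cfg.n_probes - n_special

    chroms = list(_CHROM_LENGTHS)
    lens = np.array([_CHROM_LENGTHS[c] for c in chroms], dtype=float)
    counts = np.floor(n_random * lens / lens.sum()).astype(int)
    counts[0] += n_random - counts.sum()

    rec_chrom: list[np.ndarray] = []
    rec_pos: list[np.ndarray] = []
    for c, n in zip(chroms, counts):
        pos = np.unique(rng.integers(1, _CHROM_LENGTHS[c], size=int(n * 1.02) + 8))
        # keep scattered probes out of the named regions
        for _, r in regions[regions["chrom"] == c].iterrows():
            pos = pos[(pos < r["start"]) | (pos >= r["end"])]
        pos = pos[:n]
        if len(pos) < n:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not place enough unique probe positions")
        rec_chrom.append(np.repeat(c, n))
        rec_pos.append(pos)

    chrom_arr = np.concatenate([np.array([c for _, c, _ in special_rows])] + rec_chrom)
    pos_arr = np.concatenate([np.array([p for _, _, p in special_rows])] + rec_pos)
    ids = np.array(
        [pid for pid, _, _ in special_rows]
        + [f"cg{i:08d}" for i in range(n_random)]
    )

    multi = np.zeros(cfg.n_probes, dtype=bool)
    maf = np.full(cfg.n_probes, np.nan)
    scatter = np.arange(n_special, cfg.n_probes)
    multi[rng.choice(scatter, size=int(round(cfg.multi_mapped_rate * n_random)), replace=False)] = True
    snp_idx = rng.choice(scatter, size=int(round(cfg.snp_probe_rate * n_random)), replace=False)
    maf[snp_idx] = rng.uniform(0.0, 0.5, size=len(snp_idx))

    ann = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": ids,
                "chrom": chrom_arr,
                "pos": pos_arr.astype(np.int64),
                "strand": "+",
                "multi_mapped": multi,
                "snp_maf": maf,
            }
        )
    )
    return ann, region_probes, n_special


def _baseline_profile(cfg, ann, region_probes, n_special, rng):
    """Bimodal population profile plus region-specific expectations."""
    n = cfg.n_probes
    profile = np.empty(n)
    dynamic = np.zeros(n, dtype=bool)

    scatter = np.arange(n_special, n)
    dyn_mask = rng.random(len(scatter)) < cfg.dynamic_fraction
    dyn_idx = scatter[dyn_mask]
    stat_idx = scatter[~dyn_mask]
    dynamic[dyn_idx] = True
    profile[dyn_idx] = rng.uniform(*cfg.dynamic_band, size=len(dyn_idx))
    hi = rng.random(len(stat_idx)) < 0.5
    lo_band, hi_band = cfg.static_low_band, cfg.static_high_band
    profile[stat_idx[~hi]] = rng.uniform(*lo_band, size=int((~hi).sum()))
    profile[stat_idx[hi]] = rng.uniform(*hi_band, size=int(hi.sum()))

    index = pd.Index(ann.probe_ids)
    pos_of = {p: i for i, p in enumerate(index)}
    regions = cfg.regions.frame.set_index("name")
    # intermediate bands for the candidate loci (GDF2-like promoter sits at
    # ~0.55-0.75 like the pyrosequencing-measured locus)
    candidate_bands = {
        "GDF2_promoter": (0.55, 0.75),
        "SPON2_region": (0.40, 0.60),
        "BASP1P1_region": (0.60, 0.80),
    }
    for name, ids in region_probes.items():
        idx = np.array([pos_of[p] for p in ids])
        parent = regions.loc[name, "parent_of_origin"]
        if parent == "paternal":
            profile[idx] = np.clip(rng.normal(regions.loc[name, "expected_sperm_beta"], 0.015, len(idx)), 0, 1)
        elif parent == "maternal":
            profile[idx] = np.clip(rng.normal(regions.loc[name, "expected_sperm_beta"], 0.008, len(idx)), 0, 1)
        else:
            lo, hi_ = candidate_bands.get(name, cfg.dynamic_band)
            profile[idx] = rng.uniform(lo, hi_, size=len(idx))
            dynamic[idx] = True
    return pd.Series(profile, index=index), pd.Series(dynamic, index=index)


def _implant_signatures(cfg, ann, region_probes, profile, dynamic, rng):
    """Per-cohort effect matrix (n_probes x 3) plus the truth table."""
    index = profile.index
    pos_of = {p: i for i, p in enumerate(index)}
    effects = {c: np.zeros(len(index)) for c in ("CC", "HD", "TC")}
    records = []
    flags = ann.frame
    clean = (~flags["multi_mapped"].to_numpy()) & (
        flags["snp_maf"].isna().to_numpy() | (flags["snp_maf"].to_numpy() <= 0.01)
    )
    taken = np.zeros(len(index), dtype=bool)
    for sig in cfg.signatures:
        if sig.region is not None:
            ids = region_probes[sig.region]
            for cohort, eff in sig.effects.items():
                for pid in ids:
                    records.append((sig.name, pid, cohort, float(eff)))
                    effects[cohort][pos_of[pid]] += eff
            taken[[pos_of[p] for p in ids]] = True
        else:
            pool = np.flatnonzero(dynamic.to_numpy() & clean & ~taken)
            if sig.n_sites > len(pool):
                raise ValueError(
                    f"signature {sig.name!r}: {sig.n_sites} sites exceed the "
                    f"{len(pool)} available dynamic probes"
                )
            idx = rng.choice(pool, size=sig.n_sites, replace=False)
            sign = np.where(rng.random(sig.n_sites) < sig.hypo_prob, -1.0, 1.0)
            for i, s in zip(idx, sign):
                eff = float(s * sig.magnitude)
                records.append((sig.name, index[i], sig.cohort, eff))
                effects[sig.cohort][i] += eff
            taken[idx] = True
    truth = pd.DataFrame(records, columns=["signature", "probe_id", "cohort", "effect"])
    return effects, truth


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate a cohort; identical (config, seed) gives identical output."""
    cfg = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(cfg.rng_seed)

    ann, region_probes, n_special = _build_annotation(cfg, rng)
    profile, dynamic = _baseline_profile(cfg, ann, region_probes, n_special, rng)
    effects, sig_truth = _implant_signatures(cfg, ann, region_probes, profile, dynamic, rng)

    subjects = (
        [(f"CC{i+1}", "CC") for i in range(cfg.n_cc)]
        + [(f"HD{i+1}", "HD") for i in range(cfg.n_hd)]
        + [(f"TC{i+1}", "TC") for i in range(cfg.n_tc)]
    )
    timepoints = tuple(float(t) for t in cfg.timepoints_months)
    sample_ids, rows = [], []
    for subj, cohort in subjects:
        for t in timepoints:
            sid = f"{subj}_m{int(t) if t == int(t) else t}"
            sample_ids.append((sid, subj, cohort, t))
            rows.append({"sample_id": sid, "subject_id": subj, "cohort": cohort, "timepoint_months": t})
    manifest = SampleManifest(pd.DataFrame(rows))

    sd = np.where(dynamic.to_numpy(), cfg.dynamic_noise_sd, cfg.static_noise_sd)

    # treatment pulse bookkeeping
    pulse_sites: dict[str, np.ndarray] = {}
    pulse_mag: dict[tuple[str, float], float] = {}
    pulse_sign: dict[str, np.ndarray] = {}
    if cfg.pulse is not None and cfg.pulse.n_sites > 0:
        pl = cfg.pulse
        flags = ann.frame
        clean = (~flags["multi_mapped"].to_numpy()) & (
            flags["snp_maf"].isna().to_numpy() | (flags["snp_maf"].to_numpy() <= 0.01)
        )
        pool = np.flatnonzero(dynamic.to_numpy() & clean)
        pool_size = min(len(pool), max(pl.n_sites, int(round(pl.n_sites / pl.pool_overlap))))
        shared_pool = rng.choice(pool, size=pool_size, replace=False)
        if pl.n_sites > pool_size:
            raise ValueError("treatment pulse n_sites exceeds available pool")
        followups = sorted(t for t in timepoints if t >= pl.onset_month)
        for subj, cohort in subjects:
            if cohort == "CC":
                continue
            idx = rng.choice(shared_pool, size=pl.n_sites, replace=False)
            pulse_sites[subj] = profile.index.to_numpy()[idx]
            # shift toward the midpoint so the pulse survives clipping
            pulse_sign[subj] = np.where(profile.to_numpy()[idx] > 0.5, -1.0, 1.0)
            persist = subj in pl.persister_subjects
            for k, t in enumerate(followups):
                mag = pl.magnitude if persist else pl.magnitude * (pl.decay ** k)
                pulse_mag[(subj, t)] = float(mag)

    # capture-mode extra alteration load in treated subjects
    extra_sites: dict[str, np.ndarray] = {}
    extra_idx: dict[str, np.ndarray] = {}
    if cfg.mode == "capture" and cfg.treated_extra_dynamic_fraction > 0:
        pool = np.flatnonzero(dynamic.to_numpy())
        n_extra = int(round(cfg.treated_extra_dynamic_fraction * cfg.n_probes))
        for subj, cohort in subjects:
            if cohort == "CC":
                continue
            idx = rng.choice(pool, size=min(n_extra, len(pool)), replace=False)
            extra_idx[subj] = idx
            extra_sites[subj] = profile.index.to_numpy()[idx]

    pos_of = {p: i for i, p in enumerate(profile.index)}
    n_samples = len(sample_ids)
    beta = np.empty((cfg.n_probes, n_samples))
    base = profile.to_numpy()
    last_tp = timepoints[-1]
    for j, (sid, subj, cohort, t) in enumerate(sample_ids):
        col = base + effects[cohort]
        noise = rng.standard_normal(cfg.n_probes) * sd
        if t > timepoints[0] and cfg.longitudinal_drift_sd > 0:
            noise += rng.standard_normal(cfg.n_probes) * cfg.longitudinal_drift_sd
        col = col + noise
        if (subj, t) in pulse_mag:
            idx = np.array([pos_of[p] for p in pulse_sites[subj]])
            col[idx] += pulse_sign[subj] * pulse_mag[(subj, t)]
        if cfg.mode == "capture" and subj in extra_idx and t == last_tp:
            idx = extra_idx[subj]
            sign = np.where(base[idx] > 0.5, -1.0, 1.0)
            col[idx] += sign * cfg.treated_extra_magnitude
        beta[:, j] = np.clip(col, 0.0, 1.0)

    beta_df = pd.DataFrame(beta, index=profile.index, columns=[s[0] for s in sample_ids])

    coverage = None
    if cfg.mode == "capture":
        k = cfg.coverage_dispersion
        p = k / (k + cfg.coverage_mean)
        coverage = pd.DataFrame(
            rng.negative_binomial(k, p, size=beta.shape).astype(np.int32),
            index=beta_df.index,
            columns=beta_df.columns,
        )

    contamination = {str(k): float(v) for k, v in cfg.contamination.items()}
    for sid, alpha in contamination.items():
        if sid not in beta_df.columns:
            raise ValueError(f"contamination target {sid!r} is not a sample id")
        soma = somatic_profile(ann, cfg.regions, profile)
        beta_df[sid] = add_contamination(beta_df[sid], alpha, soma)

    truth = SyntheticTruth(
        baseline_profile=profile,
        dynamic=dynamic,
        signature_sites=sig_truth,
        pulse_sites=pulse_sites,
        pulse_magnitude=pulse_mag,
        capture_extra_sites=extra_sites,
        contamination=contamination,
    )
    return SimulatedCohort(BetaMatrix(beta_df, coverage), manifest, ann, cfg.regions, truth)


def somatic_profile(
    annotation: ProbeAnnotation, regions: RegionSet, baseline_profile: pd.Series
) -> pd.Series:
    """Per-probe somatic-cell beta expectation.

    Inside ICRs the somatic expectation is the region's
    ``expected_somatic_beta`` (~0.5, one methylated allele); elsewhere the
    bulk somatic methylome is taken to match the baseline sperm profile.
    """
    soma = baseline_profile.copy()
    for _, r in regions.icrs().frame.iterrows():
        ids = annotation.probes_in_region(r["chrom"], int(r["start"]), int(r["end"]))
        soma.loc[soma.index.intersection(ids)] = r["expected_somatic_beta"]
    return soma


def add_contamination(betas: pd.Series, alpha: float, somatic: pd.Series) -> pd.Series:
    """Mix a sperm sample with a somatic fraction ``alpha``.

    Each beta becomes ``(1 - alpha) * beta + alpha * somatic_beta``.
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    soma = somatic.reindex(betas.index)
    return (1.0 - alpha) * betas + alpha * soma
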