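"""Domain containers and file I/O for methylome cohort analyses.

The substrate throughout the package is a *beta-value* matrix: per-CpG
methylation fractions in [0, 1] for a set of samples, with probes as rows.
Companion containers carry probe annotation (genomic position plus the
multi-mapping and SNP minor-allele-frequency flags used for probe filtering),
the sample manifest (subject / cohort / timepoint bookkeeping that enables
within-subject longitudinal contrasts), and named genomic regions such as
germline imprinting control regions (ICRs).

All genomic coordinates are 0-based, half-open (BED convention). Betas are
fractions; percent appears only at presentation layer. Missing betas stay
missing (NaN) and are excluded pairwise from statistics, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COHORTS = ("CC", "HD", "TC")

MANIFEST_REQUIRED = ("sample_id", "subject_id", "cohort", "timepoint_months")
ANNOTATION_COLUMNS = ("probe_id", "chrom", "pos", "strand", "multi_mapped", "snp_maf")
REGION_COLUMNS = (
    "chrom",
    "start",
    "end",
    "name",
    "parent_of_origin",
    "expected_sperm_beta",
    "expected_somatic_beta",
)


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples beta values, with an optional aligned coverage matrix.

    Parameters
    ----------
    beta
        DataFrame indexed by probe_id with one column per sample. Values are
        fractions in [0, 1]; NaN marks missing.
    coverage
        Optional DataFrame of non-negative read counts per CpG, aligned
        cell-for-cell with ``beta`` (sequencing-based "capture" mode only).
    """

    beta: pd.DataFrame
    coverage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.beta = self.beta.astype(float)
        vals = self.beta.to_numpy()
        bad = (vals < 0) | (vals > 1)
        if np.any(bad):
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {vals[r, c]!r} outside [0, 1] at probe "
                f"{self.beta.index[r]!r}, sample {self.beta.columns[c]!r}"
            )
        if not self.beta.index.is_unique:
            dup = self.beta.index[self.beta.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id {dup!r}")
        if self.coverage is not None:
            if not (
                self.coverage.index.equals(self.beta.index)
                and self.coverage.columns.equals(self.beta.columns)
            ):
                raise ValidationError("coverage matrix is not aligned with beta matrix")
            if (self.coverage.to_numpy() < 0).any():
                raise ValidationError("coverage contains negative counts")

    @property
    def probes(self) -> list[str]:
        return list(self.beta.index)

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        cov = self.coverage[list(sample_ids)] if self.coverage is not None else None
        return BetaMatrix(self.beta[list(sample_ids)], cov)

    def select_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        cov = self.coverage.loc[list(probe_ids)] if self.coverage is not None else None
        return BetaMatrix(self.beta.loc[list(probe_ids)], cov)


@dataclass
class SampleManifest:
    """Sample bookkeeping: subject, cohort (CC/HD/TC) and timepoint in months.

    ``timepoint_months == 0`` is the pre-treatment baseline. Optional clinical
    columns (age_years, sperm_conc, motility, smoker) ride along untouched.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest missing required columns: {missing}")
        df = df.copy()
        df["timepoint_months"] = df["timepoint_months"].astype(float)
        bad = set(df["cohort"]) - set(COHORTS)
        if bad:
            raise ValidationError(f"unknown cohort label(s): {sorted(bad)}")
        if (df["timepoint_months"] < 0).any():
            raise ValidationError("negative timepoint_months")
        if not df["sample_id"].is_unique:
            dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        dup_key = df.duplicated(subset=["subject_id", "timepoint_months"])
        if dup_key.any():
            row = df[dup_key].iloc[0]
            raise ValidationError(
                f"duplicate (subject, timepoint): ({row['subject_id']!r}, "
                f"{row['timepoint_months']})"
            )
        ncoh = df.groupby("subject_id")["cohort"].nunique()
        if (ncoh > 1).any():
            raise ValidationError(
                f"cohort differs across rows for subject(s): "
                f"{list(ncoh[ncoh > 1].index)}"
            )
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subject_id"]))

    def cohort_of(self, subject_id: str) -> str:
        sub = self.frame[self.frame["subject_id"] == subject_id]
        return str(sub["cohort"].iloc[0])

    def subjects_without_baseline(self) -> list[str]:
        """Subjects lacking a timepoint-0 sample (reported, not enforced)."""
        has = self.frame.groupby("subject_id")["timepoint_months"].min()
        return list(has[has > 0].index)

    def baseline_samples(self) -> pd.DataFrame:
        return self.frame[self.frame["timepoint_months"] == 0]

    def select(self, sample_ids: Iterable[str]) -> "SampleManifest":
        ids = set(sample_ids)
        return SampleManifest(self.frame[self.frame["sample_id"].isin(ids)])


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation and filtering flags.

    Columns: probe_id, chrom, pos (0-based), strand, multi_mapped (bool),
    snp_maf (minor allele frequency of an overlapping SNP; NaN if none).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        df = df.copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["multi_mapped"] = df["multi_mapped"].astype(bool)
        df["snp_maf"] = df["snp_maf"].astype(float)
        if (df["pos"] < 0).any():
            raise ValidationError("negative probe position")
        if not df["probe_id"].is_unique:
            dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate probe_id {dup!r}")
        maf = df["snp_maf"].dropna()
        if ((maf < 0) | (maf > 1)).any():
            raise ValidationError("snp_maf outside [0, 1]")
        self.frame = df.reset_index(drop=True)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.frame["probe_id"])

    def indexed(self) -> pd.DataFrame:
        return self.frame.set_index("probe_id")

    def probes_in_region(self, chrom: str, start: int, end: int) -> list[str]:
        """Probe ids whose position falls in [start, end) on ``chrom``."""
        df = self.frame
        m = (df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)
        return list(df.loc[m, "probe_id"])


@dataclass
class RegionSet:
    """Named genomic intervals with optional imprinting metadata.

    ICR entries carry ``parent_of_origin`` in {paternal, maternal} and both
    expected betas: the sperm expectation (~1 for paternally methylated ICRs
    like H19, ~0 for maternally methylated ones like MEST/KCNQ1OT1/SNRPN) and
    the somatic expectation (~0.5, one methylated allele in somatic tissue).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in REGION_COLUMNS:
            if col not in df.columns:
                if col == "parent_of_origin":
                    df[col] = "none"
                elif col in ("expected_sperm_beta", "expected_somatic_beta"):
                    df[col] = np.nan
                else:
                    raise ValidationError(f"region set missing column {col!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["parent_of_origin"] = df["parent_of_origin"].fillna("none")
        if (df["start"] >= df["end"]).any():
            row = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"region {row['name']!r}: start {row['start']} >= end {row['end']}"
            )
        bad = set(df["parent_of_origin"]) - {"paternal", "maternal", "none"}
        if bad:
            raise ValidationError(f"unknown parent_of_origin: {sorted(bad)}")
        icr = df[df["parent_of_origin"] != "none"]
        if icr[["expected_sperm_beta", "expected_somatic_beta"]].isna().any(axis=None):
            raise ValidationError("ICR region lacks expected sperm/somatic beta")
        if not df["name"].is_unique:
            dup = df["name"][df["name"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate region name {dup!r}")
        self.frame = df[list(REGION_COLUMNS)].reset_index(drop=True)

    @property
    def names(self) -> list[str]:
        return list(self.frame["name"])

    def icrs(self) -> "RegionSet":
        return RegionSet(self.frame[self.frame["parent_of_origin"] != "none"])

    def get(self, name: str) -> pd.Series:
        sub = self.frame[self.frame["name"] == name]
        if sub.empty:
            raise KeyError(f"no region named {name!r}")
        return sub.iloc[0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_beta_matrix(path: str | Path, coverage_path: str | Path | None = None) -> BetaMatrix:
    """Read a beta matrix TSV (col 1 = probe_id, header row = sample ids).

    Empty cells are missing values (NaN), not zeros. Values outside [0, 1]
    or non-numeric cells are rejected with the offending line named.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    beta = pd.DataFrame(index=raw.index.astype(str))
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
            raise ParseError(
                f"{path.name}, line {line}: non-numeric value "
                f"{raw.loc[bad, col].iloc[0]!r} in column {col!r}"
            )
        beta[col] = converted
    cov = None
    if coverage_path is not None:
        cov = pd.read_csv(coverage_path, sep="\t", index_col=0)
        cov.index = cov.index.astype(str)
    return BetaMatrix(beta, cov)


def write_beta_matrix(bm: BetaMatrix, path: str | Path, coverage_path: str | Path | None = None) -> None:
    bm.beta.to_csv(path, sep="\t", index_label="probe_id", na_rep="")
    if bm.coverage is not None and coverage_path is not None:
        bm.coverage.to_csv(coverage_path, sep="\t", index_label="probe_id")


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a sample manifest CSV and validate it.

    Subjects without a baseline (timepoint 0) sample are reported via a
    warning but accepted.
    """
    df = pd.read_csv(path)
    manifest = SampleManifest(df)
    nobase = manifest.subjects_without_baseline()
    if nobase:
        warnings.warn(f"subjects without baseline sample: {nobase}", stacklevel=2)
    return manifest


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    cols = [c for c in MANIFEST_REQUIRED if c in manifest.frame.columns]
    extra = [c for c in manifest.frame.columns if c not in cols]
    manifest.frame[cols + extra].to_csv(path, index=False)


def read_regions(path: str | Path) -> RegionSet:
    """Read a BED-like region file (chrom start end name [parent sperm somatic]).

    '.' marks a missing metadata value. Coordinates are 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"line {i}: expected >= 4 BED columns, got {len(parts)}")
            rec = {
                "chrom": parts[0],
                "start": int(parts[1]),
                "end": int(parts[2]),
                "name": parts[3],
                "parent_of_origin": "none",
                "expected_sperm_beta": np.nan,
                "expected_somatic_beta": np.nan,
            }
            if len(parts) > 4 and parts[4] != ".":
                rec["parent_of_origin"] = parts[4]
            if len(parts) > 5 and parts[5] != ".":
                rec["expected_sperm_beta"] = float(parts[5])
            if len(parts) > 6 and parts[6] != ".":
                rec["expected_somatic_beta"] = float(parts[6])
            rows.append(rec)
    return RegionSet(pd.DataFrame(rows))


def write_regions(regions: RegionSet, path: str | Path) -> None:
    df = regions.frame
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            sperm = "." if pd.isna(r["expected_sperm_beta"]) else repr(float(r["expected_sperm_beta"]))
            soma = "." if pd.isna(r["expected_somatic_beta"]) else repr(float(r["expected_somatic_beta"]))
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['name']}\t"
                f"{r['parent_of_origin']}\t{sperm}\t{soma}\n"
            )


def read_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"probe_id": str, "chrom": str, "strand": str},
    )
    return ProbeAnnotation(df)


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.frame[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False, na_rep="")


def check_probe_universe(bm: BetaMatrix, annotation: ProbeAnnotation) -> None:
    """Every probe referenced by the beta matrix must exist in the annotation."""
    known = set(annotation.frame["probe_id"])
    unknown = [p for p in bm.probes if p not in known]
    if unknown:
        raise ValidationError(
            f"{len(unknown)} beta-matrix probes absent from annotation "
            f"(first: {unknown[0]!r})"
        )
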