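"""Core typed containers for methylation-array analysis.

The pipeline operates on four kinds of tabular objects: a probe-by-sample
beta-value matrix, a sample annotation sheet, a CpG annotation manifest and
sparse linear clocks.  Each wrapper validates its invariants at construction
so downstream stages can assume clean inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

SPECIES = frozenset({"cattle", "human"})
TISSUES = frozenset({"blood", "oocyte", "skin"})
REGION_CLASSES = frozenset(
    {
        "promoter",
        "five_prime_utr",
        "exon",
        "intron",
        "three_prime_utr",
        "intergenic_upstream",
        "intergenic_downstream",
    }
)
ISLAND_STATUSES = frozenset({"island", "non_island"})

# Promoter definition: −10 kb to +1000 bp around the nearest TSS.
PROMOTER_WINDOW = (-10_000, 1_000)


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


def _check_unique(values: pd.Series, what: str) -> None:
    dup = values[values.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate {what}: {sorted(set(dup))[:5]}")


class SampleTable:
    """Per-sample annotations: species, tissue, age, lifespan, donor linkage.

    Wraps a DataFrame with columns ``sample_id``, ``species``, ``tissue``,
    ``age_years``, ``max_lifespan_years`` and optional ``donor_id``.
    """

    REQUIRED = ("sample_id", "species", "tissue", "age_years", "max_lifespan_years")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        df = df.copy().reset_index(drop=True)
        df["sample_id"] = df["sample_id"].astype(str)
        df["species"] = df["species"].astype(str).str.strip().str.lower()
        df["tissue"] = df["tissue"].astype(str).str.strip().str.lower()
        if "donor_id" not in df.columns:
            df["donor_id"] = pd.NA

        _check_unique(df["sample_id"], "sample_id")
        bad_sp = sorted(set(df["species"]) - SPECIES)
        if bad_sp:
            raise ValidationError(f"unknown species token(s): {bad_sp}")
        bad_ti = sorted(set(df["tissue"]) - TISSUES)
        if bad_ti:
            raise ValidationError(f"unknown tissue token(s): {bad_ti}")

        df["age_years"] = pd.to_numeric(df["age_years"])
        df["max_lifespan_years"] = pd.to_numeric(df["max_lifespan_years"])
        bad = df.loc[df["age_years"] <= 0, "sample_id"]
        if len(bad):
            raise ValidationError(f"nonpositive age for sample(s): {list(bad)[:5]}")
        bad = df.loc[df["age_years"] > df["max_lifespan_years"], "sample_id"]
        if len(bad):
            raise ValidationError(
                f"age exceeds maximum lifespan for sample(s): {list(bad)[:5]}"
            )
        for sp, grp in df.groupby("species"):
            if grp["max_lifespan_years"].nunique() > 1:
                raise ValidationError(
                    f"species {sp!r} has inconsistent max_lifespan_years: "
                    f"{sorted(grp['max_lifespan_years'].unique())}"
                )
        donors = df.dropna(subset=["donor_id"])
        for donor, grp in donors.groupby("donor_id"):
            if grp["species"].nunique() > 1 or grp["age_years"].nunique() > 1:
                raise ValidationError(
                    f"donor {donor!r} linked to samples with differing species or age"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    @property
    def ages(self) -> np.ndarray:
        return self.df["age_years"].to_numpy(float)

    @property
    def lifespans(self) -> np.ndarray:
        return self.df["max_lifespan_years"].to_numpy(float)

    def lifespan_of(self, species: str) -> float:
        sub = self.df.loc[self.df["species"] == species, "max_lifespan_years"]
        if sub.empty:
            raise ValidationError(f"no samples of species {species!r}")
        return float(sub.iloc[0])

    def subset(self, *, tissue: str | None = None, species: str | None = None,
               sample_ids=None) -> "SampleTable":
        df = self.df
        if tissue is not None:
            df = df[df["tissue"] == tissue]
        if species is not None:
            df = df[df["species"] == species]
        if sample_ids is not None:
            keep = set(sample_ids)
            df = df[df["sample_id"].isin(keep)]
        return SampleTable(df)


class BetaMatrix:
    """Probe-by-sample matrix of methylation beta values in [0, 1]."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        _check_unique(df.index.to_series(), "probe_id")
        _check_unique(df.columns.to_series(), "sample_id")
        values = df.to_numpy(float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing beta value at probe {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        bad = (values < -1e-9) | (values > 1 + 1e-9)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {values[r, c]} outside [0,1] at probe "
                f"{df.index[r]!r}, sample {df.columns[c]!r}"
            )
        # tolerate float-formatting fuzz within 1e-9 of the bounds
        self.df = df.clip(0.0, 1.0)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def samples_matrix(self, samples: SampleTable) -> np.ndarray:
        """n_samples × n_probes array in the order of `samples`."""
        missing = [s for s in samples.sample_ids if s not in self.df.columns]
        if missing:
            raise ValidationError(f"samples absent from beta matrix: {missing[:5]}")
        return self.df[samples.sample_ids].to_numpy(float).T

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.df[list(sample_ids)])


class CpGAnnotation:
    """Probe manifest: genomic location, nearest gene, region and island status."""

    REQUIRED = (
        "probe_id",
        "chromosome",
        "position",
        "nearest_gene",
        "distance_to_tss",
        "region_class",
        "island_status",
    )

    def __init__(self, df: pd.DataFrame, *, check_promoter_window: bool = True):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        df = df.copy().reset_index(drop=True)
        df["probe_id"] = df["probe_id"].astype(str)
        _check_unique(df["probe_id"], "probe_id")
        df["chromosome"] = df["chromosome"].astype(str)
        df["position"] = pd.to_numeric(df["position"]).astype(int)
        df["distance_to_tss"] = pd.to_numeric(df["distance_to_tss"]).astype(int)
        df["region_class"] = df["region_class"].astype(str).str.strip().str.lower()
        df["island_status"] = df["island_status"].astype(str).str.strip().str.lower()
        bad = sorted(set(df["region_class"]) - REGION_CLASSES)
        if bad:
            raise ValidationError(f"unknown region_class token(s): {bad}")
        bad = sorted(set(df["island_status"]) - ISLAND_STATUSES)
        if bad:
            raise ValidationError(f"unknown island_status token(s): {bad}")
        if (df["position"] < 1).any():
            raise ValidationError("positions must be 1-based positive integers")
        if check_promoter_window:
            lo, hi = PROMOTER_WINDOW
            in_window = df["distance_to_tss"].between(lo, hi)
            inconsistent = (df["region_class"] == "promoter") != in_window
            n_bad = int(inconsistent.sum())
            if n_bad:
                warnings.warn(
                    f"{n_bad} probe(s) have region_class inconsistent with the "
                    f"promoter window [{lo}, {hi}] bp around the TSS",
                    stacklevel=2,
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.df["probe_id"])

    def island_probes(self) -> set[str]:
        return set(self.df.loc[self.df["island_status"] == "island", "probe_id"])

    def probes_with(self, column: str, value) -> set[str]:
        return set(self.df.loc[self.df[column] == value, "probe_id"])


@dataclass
class Clock:
    """A sparse linear DNA-methylation age predictor.

    ``transform`` maps chronological age to the regression response (years,
    relative age, or a log-linear scale); ``coefficients`` are on the original
    beta scale.
    """

    transform: "object"  # AgeTransform; typed loosely to avoid a cycle
    intercept: float
    coefficients: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = np.array(list(self.coefficients.values()), float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValidationError("clock coefficients must be finite")
        if not np.isfinite(self.intercept):
            raise ValidationError("clock intercept must be finite")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)

    def linear_response(self, betas: BetaMatrix) -> pd.Series:
        """Transformed-age prediction (before back-transform), per sample."""
        probes = self.probe_ids
        missing = [p for p in probes if p not in betas.df.index]
        if missing:
            raise ValidationError(
                f"{len(missing)} clock probe(s) missing from beta matrix: {missing[:10]}"
            )
        if probes:
            w = np.array([self.coefficients[p] for p in probes])
            yhat = self.intercept + betas.df.loc[probes].to_numpy(float).T @ w
        else:
            yhat = np.full(len(betas.sample_ids), self.intercept)
        return pd.Series(yhat, index=betas.sample_ids, name="response")


@dataclass
class EnrichmentResult:
    """2×2 feature-vs-selection table with odds ratio and hypergeometric p."""

    a: int  # feature ∩ selected
    b: int  # ¬feature ∩ selected
    c: int  # feature ∩ background-only
    d: int  # ¬feature ∩ background-only
    odds_ratio: float
    p_value: float
    odds_ratio_infinite: bool = False

    @property
    def n_selected(self) -> int:
        return self.a + self.b

    @property
    def n_background(self) -> int:
        return self.a + self.b + self.c + self.d
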