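"""Synthetic mammalian-methylation-array data with known aging structure.

The generator emulates the statistical features the downstream analyses
depend on, with ground truth for every probe:

* two cattle tissues (blood, oocytes) with disjoint sets of age-related
  CpGs, plus small "shared" (concordant) and "divergent" (opposite-sign)
  classes;
* lower baseline methylation in oocytes than blood at non-island CpGs, and
  low baselines at island CpGs in both tissues;
* an optional second species (human blood) whose age signal at blood probes
  is shared on the relative-age scale — equal drift per unit of
  age / maximum-lifespan — so dual-species clocks are learnable;
* a toy genome layout (chromosome, position, nearest gene, TSS distance,
  region class, island status) rich enough to exercise promoter enrichment
  and gene-neighbourhood queries.

Betas are baseline + slope × age + Gaussian noise, clipped to [0, 1].
Slopes are stated per cattle year; for a species with maximum lifespan M
the per-year slope is scaled by (38 / M) so the drift per relative-age unit
is identical across species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, CpGAnnotation, SampleTable

CATTLE_LIFESPAN = 38.0
HUMAN_LIFESPAN = 122.5

PROBE_CLASSES = (
    "null",
    "blood_up",
    "blood_down",
    "oocyte_up",
    "oocyte_down",
    "shared",
    "divergent",
)


@dataclass
class SimulationConfig:
    """Study-design parameters for the generator.

    Defaults are a desk-scale mirror of a two-tissue cattle cohort with a
    human blood panel: 2,000 probes, 60 cattle blood + 40 cattle oocyte +
    60 human blood samples, cattle ages 0.5–13.3 y, human ages 1–100 y,
    maximum lifespans 38 and 122.5 y.  Slopes are drawn uniformly from
    ``slope_range`` (beta per cattle year) with random sign fixed by class;
    noise is additive Gaussian on the beta scale (sd ``noise_sd``).
    """

    n_probes: int = 2000
    n_cattle_blood: int = 60
    n_cattle_oocyte: int = 40
    n_human_blood: int = 60
    cattle_age_range: tuple[float, float] = (0.5, 13.3)
    human_age_range: tuple[float, float] = (1.0, 100.0)
    cattle_lifespan: float = CATTLE_LIFESPAN
    human_lifespan: float = HUMAN_LIFESPAN

    # probe-class counts; the remainder of n_probes is null
    n_blood_up: int = 60
    n_blood_down: int = 60
    n_oocyte_up: int = 40
    n_oocyte_down: int = 40
    n_shared: int = 20
    n_divergent: int = 20

    slope_range: tuple[float, float] = (0.005, 0.02)  # beta per cattle year
    noise_sd: float = 0.02

    island_fraction: float = 0.3
    island_fraction_blood_up: float = 0.6  # blood hypermethylation favours islands
    promoter_fraction_blood_up: float = 0.5
    promoter_fraction_background: float = 0.1
    island_baseline_range: tuple[float, float] = (0.05, 0.25)
    blood_nonisland_baseline_range: tuple[float, float] = (0.55, 0.85)
    oocyte_nonisland_baseline_range: tuple[float, float] = (0.35, 0.65)

    # isogenic-pair options
    donor_acceleration_sd: float = 1.5  # years
    acceleration_correlation: float = 0.0  # cross-tissue ρ of donor offsets

    seed: int | None = None

    def __post_init__(self):
        counts = (
            self.n_blood_up
            + self.n_blood_down
            + self.n_oocyte_up
            + self.n_oocyte_down
            + self.n_shared
            + self.n_divergent
        )
        if counts > self.n_probes:
            raise ValueError("probe-class counts exceed n_probes")
        lo, hi = self.slope_range
        if lo < 0 or hi < lo:
            raise ValueError("slope_range must be nonnegative and ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


class SimulatedDataset(NamedTuple):
    betas: BetaMatrix
    samples: SampleTable
    annotation: CpGAnnotation
    truth: pd.DataFrame


def _draw_classes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    classes = np.array(["null"] * config.n_probes, dtype=object)
    counts = [
        ("blood_up", config.n_blood_up),
        ("blood_down", config.n_blood_down),
        ("oocyte_up", config.n_oocyte_up),
        ("oocyte_down", config.n_oocyte_down),
        ("shared", config.n_shared),
        ("divergent", config.n_divergent),
    ]
    order = rng.permutation(config.n_probes)
    pos = 0
    for label, n in counts:
        classes[order[pos : pos + n]] = label
        pos += n
    return classes


def _draw_slopes(classes: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe (blood, oocyte) slopes in beta per cattle year."""
    n = len(classes)
    lo, hi = config.slope_range
    mag = rng.uniform(lo, hi, size=(n, 2))
    s_blood = np.zeros(n)
    s_oocyte = np.zeros(n)
    sign = rng.choice([-1.0, 1.0], size=n)
    s_blood[classes == "blood_up"] = mag[classes == "blood_up", 0]
    s_blood[classes == "blood_down"] = -mag[classes == "blood_down", 0]
    s_oocyte[classes == "oocyte_up"] = mag[classes == "oocyte_up", 1]
    s_oocyte[classes == "oocyte_down"] = -mag[classes == "oocyte_down", 1]
    sh = classes == "shared"
    s_blood[sh] = sign[sh] * mag[sh, 0]
    s_oocyte[sh] = sign[sh] * mag[sh, 1]
    dv = classes == "divergent"
    s_blood[dv] = sign[dv] * mag[dv, 0]
    s_oocyte[dv] = -sign[dv] * mag[dv, 1]
    return s_blood, s_oocyte


def _feasible_baseline(base: np.ndarray, slope: np.ndarray, drift_span: float) -> np.ndarray:
    """Shift baselines so baseline + slope×age stays inside [0.02, 0.98]."""
    drift = slope * drift_span
    out = base.copy()
    up = slope > 0
    out[up] = np.minimum(out[up], 0.98 - drift[up])
    dn = slope < 0
    out[dn] = np.maximum(out[dn], 0.02 - drift[dn])
    return np.clip(out, 0.02, 0.98)


def _make_annotation(probe_ids, classes, island, config, rng) -> CpGAnnotation:
    n = len(probe_ids)
    n_chrom = 29
    chrom = np.array([str(i % n_chrom + 1) for i in range(n)], dtype=object)
    # probes laid down every 10 kb along each toy chromosome
    within = np.zeros(n, int)
    seen: dict[str, int] = {}
    for i, c in enumerate(chrom):
        seen[c] = seen.get(c, 0) + 1
        within[i] = seen[c]
    position = within * 10_000 + 1

    promoter_p = np.where(
        classes == "blood_up",
        config.promoter_fraction_blood_up,
        config.promoter_fraction_background,
    )
    is_promoter = rng.random(n) < promoter_p
    distance = np.zeros(n, int)
    region = np.empty(n, dtype=object)
    body_classes = np.array(["five_prime_utr", "exon", "intron", "three_prime_utr"])
    for i in range(n):
        if is_promoter[i]:
            distance[i] = rng.integers(-10_000, 1_001)
            region[i] = "promoter"
        else:
            kind = rng.random()
            if kind < 0.5:
                distance[i] = rng.integers(1_001, 50_001)
                region[i] = str(rng.choice(body_classes))
            elif kind < 0.75:
                distance[i] = rng.integers(50_001, 200_001)
                region[i] = "intergenic_downstream"
            else:
                distance[i] = -rng.integers(10_001, 200_001)
                region[i] = "intergenic_upstream"

    # gene symbols: blocks of neighbouring probes share a nearest gene
    gene = np.array(
        [f"GENE{(i // 5) + 1:04d}" for i in range(n)], dtype=object
    )
    df = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chrom,
            "position": position,
            "nearest_gene": gene,
            "distance_to_tss": distance,
            "region_class": region,
            "island_status": np.where(island, "island", "non_island"),
        }
    )
    return CpGAnnotation(df)


def _species_slope_factor(lifespan: float, config: SimulationConfig) -> float:
    # equal drift per relative-age unit across species
    return config.cattle_lifespan / lifespan


def _build_samples(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    counter = 0

    def add(n, species, tissue, age_range, lifespan):
        nonlocal counter
        ages = rng.uniform(*age_range, size=n)
        for a in ages:
            counter += 1
            rows.append(
                {
                    "sample_id": f"S{counter:04d}",
                    "species": species,
                    "tissue": tissue,
                    "age_years": round(float(a), 4),
                    "max_lifespan_years": lifespan,
                    "donor_id": pd.NA,
                }
            )

    add(config.n_cattle_blood, "cattle", "blood", config.cattle_age_range, config.cattle_lifespan)
    add(config.n_cattle_oocyte, "cattle", "oocyte", config.cattle_age_range, config.cattle_lifespan)
    add(config.n_human_blood, "human", "blood", config.human_age_range, config.human_lifespan)
    return pd.DataFrame(rows)


def _signal_matrix(
    sample_df: pd.DataFrame,
    baselines: dict[str, np.ndarray],
    slopes: dict[str, np.ndarray],
    config: SimulationConfig,
    effective_age: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free probe × sample signal."""
    n_probes = len(next(iter(baselines.values())))
    signal = np.zeros((n_probes, len(sample_df)))
    ages = (
        sample_df["age_years"].to_numpy(float)
        if effective_age is None
        else effective_age
    )
    for j, (_, row) in enumerate(sample_df.iterrows()):
        tissue = row["tissue"]
        base = baselines.get(tissue)
        slope = slopes.get(tissue)
        if base is None:
            raise ValueError(f"no baseline model for tissue {row['tissue']!r}")
        factor = _species_slope_factor(float(row["max_lifespan_years"]), config)
        signal[:, j] = base + slope * factor * ages[j]
    return signal


def _assemble(config, rng, sample_df, effective_age=None) -> SimulatedDataset:
    n = config.n_probes
    classes = _draw_classes(config, rng)
    s_blood, s_oocyte = _draw_slopes(classes, config, rng)

    island_p = np.where(
        classes == "blood_up", config.island_fraction_blood_up, config.island_fraction
    )
    island = rng.random(n) < island_p

    base_island = rng.uniform(*config.island_baseline_range, size=n)
    base_blood = np.where(
        island, base_island, rng.uniform(*config.blood_nonisland_baseline_range, size=n)
    )
    base_oocyte = np.where(
        island, base_island, rng.uniform(*config.oocyte_nonisland_baseline_range, size=n)
    )

    # widest drift any sampled individual can produce, per tissue
    tissues = set(sample_df["tissue"])
    blood_span = 0.0
    if "blood" in tissues:
        blood_span = config.cattle_age_range[1]
        if (sample_df["species"] == "human").any():
            blood_span = max(
                blood_span,
                config.human_age_range[1]
                * _species_slope_factor(config.human_lifespan, config),
            )
    oocyte_span = config.cattle_age_range[1] if "oocyte" in tissues else 0.0
    base_blood = _feasible_baseline(base_blood, s_blood, blood_span)
    base_oocyte = _feasible_baseline(base_oocyte, s_oocyte, oocyte_span)

    probe_ids = [f"cg{i:06d}" for i in range(1, n + 1)]
    annotation = _make_annotation(probe_ids, classes, island, config, rng)

    baselines = {"blood": base_blood, "oocyte": base_oocyte}
    slopes = {"blood": s_blood, "oocyte": s_oocyte}
    signal = _signal_matrix(sample_df, baselines, slopes, config, effective_age)

    infeasible = np.mean((signal < 0) | (signal > 1))
    if infeasible > 0.5:
        warnings.warn(
            f"{infeasible:.0%} of noise-free signal falls outside [0,1]; "
            "baselines and slopes are jointly infeasible"
        )

    noise = rng.normal(0.0, config.noise_sd, size=signal.shape) if config.noise_sd > 0 else 0.0
    raw = signal + noise
    clipped_fraction = float(np.mean((raw < 0) | (raw > 1)))
    beta = np.clip(raw, 0.0, 1.0)

    betas = BetaMatrix(
        pd.DataFrame(beta, index=probe_ids, columns=sample_df["sample_id"].tolist())
    )
    samples = SampleTable(sample_df)
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "class": classes,
            "slope_blood": s_blood,
            "slope_oocyte": s_oocyte,
            "baseline_blood": base_blood,
            "baseline_oocyte": base_oocyte,
            "island_status": np.where(island, "island", "non_island"),
        }
    ).set_index("probe_id")
    truth.attrs["clipped_fraction"] = clipped_fraction
    return SimulatedDataset(betas, samples, annotation, truth)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset under ``config``; ``config.seed`` is mandatory."""
    if config.seed is None:
        raise ValueError("SimulationConfig.seed must be set for reproducibility")
    rng = np.random.default_rng(config.seed)
    n_total = config.n_cattle_blood + config.n_cattle_oocyte + config.n_human_blood
    if n_total == 0:
        raise ValueError("no samples requested")
    for name in ("n_cattle_blood", "n_cattle_oocyte", "n_human_blood"):
        if getattr(config, name) < 0:
            raise ValueError(f"{name} must be nonnegative")
    sample_df = _build_samples(config, rng)
    return _assemble(config, rng, sample_df)


def simulate_isogenic_pairs(config: SimulationConfig, n_donors: int | None = None) -> SimulatedDataset:
    """Paired design: each cattle donor contributes one blood and one oocyte sample.

    A per-donor latent age-acceleration offset (years, sd
    ``donor_acceleration_sd``) is added to the age entering the methylation
    signal — not to the recorded chronological age — with cross-tissue
    correlation ``acceleration_correlation``.
    """
    if config.seed is None:
        raise ValueError("SimulationConfig.seed must be set for reproducibility")
    if n_donors is None:
        total = config.n_cattle_blood + config.n_cattle_oocyte
        if total % 2:
            raise ValueError("odd sample budget cannot form blood/oocyte pairs")
        n_donors = total // 2
    if n_donors < 1:
        raise ValueError("need at least one donor")
    rng = np.random.default_rng(config.seed)

    ages = rng.uniform(*config.cattle_age_range, size=n_donors)
    rho = config.acceleration_correlation
    cov = config.donor_acceleration_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    accel = (
        rng.multivariate_normal([0.0, 0.0], cov, size=n_donors)
        if config.donor_acceleration_sd > 0
        else np.zeros((n_donors, 2))
    )

    rows = []
    eff = []
    for d in range(n_donors):
        for k, tissue in enumerate(("blood", "oocyte")):
            rows.append(
                {
                    "sample_id": f"D{d + 1:03d}_{tissue}",
                    "species": "cattle",
                    "tissue": tissue,
                    "age_years": round(float(ages[d]), 4),
                    "max_lifespan_years": config.cattle_lifespan,
                    "donor_id": f"D{d + 1:03d}",
                }
            )
            eff.append(float(ages[d]) + accel[d, k])
    sample_df = pd.DataFrame(rows)
    paired_config = replace(
        config,
        n_cattle_blood=n_donors,
        n_cattle_oocyte=n_donors,
        n_human_blood=0,
        seed=config.seed,
    )
    ds = _assemble(paired_config, rng, sample_df, effective_age=np.array(eff))
    ds.truth.attrs["donor_acceleration"] = pd.DataFrame(
        accel,
        index=[f"D{d + 1:03d}" for d in range(n_donors)],
        columns=["blood", "oocyte"],
    )
    return ds
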