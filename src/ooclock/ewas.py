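"""Per-CpG aging EWAS, cross-tissue meta-analysis and enrichment statistics.

Within one tissue each probe is screened by the Pearson correlation of its
beta values with chronological age in years:

    t = r * sqrt(n - 2) / sqrt(1 - r^2),   p two-sided from Student t(n-2),
    Z = sign(r) * Phi^{-1}(1 - p/2).

Tissue results are combined with Stouffer's method,
z_meta = (w1 z1 + w2 z2) / sqrt(w1^2 + w2^2) (unit weights by default).
Selection uses a fixed p < 1e-4 threshold with at most 500 probes per
direction of change, ranked by |Z|.  Enrichment of a probe feature (e.g.
promoter location) in a selected set is scored by the 2x2 odds ratio and an
exact upper-tail hypergeometric p-value.
"""

from __future__ import annotations

import difflib
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    BetaMatrix,
    CpGAnnotation,
    EnrichmentResult,
    SampleTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

P_THRESHOLD = 1e-4
MAX_PER_DIRECTION = 500

# Smallest p we convert to Z: below this, Z is capped so it stays finite.
_P_FLOOR = 1e-300
Z_MAX = float(stats.norm.isf(_P_FLOOR / 2))

EWAS_COLUMNS = ("n", "r", "t", "p", "z")


def correlation_screen(
    betas: BetaMatrix, samples: SampleTable, tissue: str | None = None
) -> pd.DataFrame:
    """Per-probe Pearson correlation with age for one tissue's samples.

    Probes with zero variance get NaN statistics and are excluded from
    downstream selection; their count is logged.
    """
    if tissue is not None:
        samples = samples.subset(tissue=tissue)
    n = len(samples)
    if n < 4:
        raise ValidationError(f"screening needs >=4 samples, got {n}")
    X = betas.samples_matrix(samples)  # n × p
    age = samples.ages
    if np.ptp(age) == 0:
        raise ValidationError("age is constant; correlation screen undefined")

    xc = X - X.mean(axis=0)
    yc = age - age.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    defined = sx > 0
    r = np.full(X.shape[1], np.nan)
    r[defined] = (xc[:, defined] * yc[:, None]).sum(axis=0) / (sx[defined] * sy)
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # |r| = 1 gives t = ±inf and p = 0; floor p so Z stays finite
    p = np.where(np.isnan(r), np.nan, np.maximum(p, _P_FLOOR))
    z = np.sign(r) * np.minimum(stats.norm.isf(p / 2.0), Z_MAX)

    n_undefined = int((~defined).sum())
    if n_undefined:
        logger.info("correlation_screen: %d constant probe(s) excluded", n_undefined)
    return pd.DataFrame(
        {"n": n, "r": r, "t": t, "p": p, "z": z},
        index=pd.Index(betas.probe_ids, name="probe_id"),
    )


def stouffer_meta(z1, z2, weights: tuple[float, float] = (1.0, 1.0)):
    """Stouffer-combined Z: (w1 z1 + w2 z2) / sqrt(w1^2 + w2^2)."""
    w1, w2 = weights
    denom = np.sqrt(w1**2 + w2**2)
    if denom == 0:
        raise ValidationError("Stouffer weights must not both be zero")
    out = (w1 * np.asarray(z1, float) + w2 * np.asarray(z2, float)) / denom
    return float(out) if out.ndim == 0 else out


def meta_analysis(
    ewas_blood: pd.DataFrame,
    ewas_oocyte: pd.DataFrame,
    weighting: str = "equal",
) -> pd.DataFrame:
    """Combine two per-tissue EWAS tables probe-wise with Stouffer's method.

    ``weighting`` is "equal" or "sqrt_n" (weights sqrt of each tissue's n).
    A probe undefined in either tissue has undefined meta statistics.
    """
    _check_same_probes(ewas_blood, ewas_oocyte)
    z1 = ewas_blood["z"].to_numpy(float)
    z2 = ewas_oocyte["z"].reindex(ewas_blood.index).to_numpy(float)
    if weighting == "equal":
        w = (1.0, 1.0)
    elif weighting == "sqrt_n":
        w = (
            float(np.sqrt(ewas_blood["n"].iloc[0])),
            float(np.sqrt(ewas_oocyte["n"].iloc[0])),
        )
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    z_meta = stouffer_meta(z1, z2, w)
    p_meta = np.maximum(2.0 * stats.norm.sf(np.abs(z_meta)), _P_FLOOR)
    p_meta = np.where(np.isnan(z_meta), np.nan, p_meta)
    out = pd.DataFrame({"z_meta": z_meta, "p_meta": p_meta}, index=ewas_blood.index)
    return out


def select_top_cpgs(
    ewas: pd.DataFrame,
    p_threshold: float = P_THRESHOLD,
    max_per_direction: int = MAX_PER_DIRECTION,
    p_col: str = "p",
    z_col: str = "z",
) -> dict[str, list[str]]:
    """Significant probes split by direction, capped per direction by |Z|.

    Ties in |Z| are broken by probe_id so the selection is deterministic.
    """
    sig = ewas[(ewas[p_col] < p_threshold) & ewas[z_col].notna()]
    hyper = sig[sig[z_col] > 0]
    hypo = sig[sig[z_col] < 0]

    def ranked_ids(sub: pd.DataFrame) -> list[str]:
        order = sorted(sub.index, key=lambda pid: (-abs(sub.loc[pid, z_col]), pid))
        return order[:max_per_direction]

    return {"hyper": ranked_ids(hyper), "hypo": ranked_ids(hypo)}


def _check_same_probes(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if set(a.index) != set(b.index):
        raise ValidationError("EWAS tables cover different probe universes")


def classify_divergent(
    ewas_blood: pd.DataFrame,
    ewas_oocyte: pd.DataFrame,
    p_threshold: float = P_THRESHOLD,
) -> pd.Series:
    """Per-probe cross-tissue aging class.

    ``divergent_both`` requires significance in both tissues with opposite
    directions of change; ``concordant_both`` the same with equal signs.
    """
    _check_same_probes(ewas_blood, ewas_oocyte)
    oo = ewas_oocyte.reindex(ewas_blood.index)
    sig_b = (ewas_blood["p"] < p_threshold) & ewas_blood["z"].notna()
    sig_o = (oo["p"] < p_threshold) & oo["z"].notna()
    same_sign = np.sign(ewas_blood["z"]) == np.sign(oo["z"])
    cls = pd.Series("neither", index=ewas_blood.index, name="divergence_class")
    cls[sig_b & ~sig_o] = "blood_only"
    cls[~sig_b & sig_o] = "oocyte_only"
    cls[sig_b & sig_o & same_sign] = "concordant_both"
    cls[sig_b & sig_o & ~same_sign] = "divergent_both"
    return cls


def cross_tissue_z_correlation(
    ewas_blood: pd.DataFrame, ewas_oocyte: pd.DataFrame
) -> float:
    """Pearson correlation of the two tissues' Z vectors over defined probes."""
    _check_same_probes(ewas_blood, ewas_oocyte)
    z = pd.DataFrame(
        {"b": ewas_blood["z"], "o": ewas_oocyte["z"].reindex(ewas_blood.index)}
    ).dropna()
    if len(z) < 10:
        raise ValidationError("need >=10 probes with defined Z in both tissues")
    return float(np.corrcoef(z["b"], z["o"])[0, 1])


def feature_enrichment(selected, background, feature) -> EnrichmentResult:
    """Odds ratio and exact hypergeometric p for a feature within a selection.

    ``feature`` is the set of background probes carrying the feature (or a
    boolean Series indexed by probe).  The p-value is the upper tail
    P(X >= a) of the hypergeometric distribution with population =
    |background|, successes = |feature ∩ background|, draws = |selected|.
    """
    selected = set(selected)
    background = set(background)
    if not selected <= background:
        raise ValidationError("selected probes must be a subset of the background")
    if isinstance(feature, pd.Series):
        undefined = background - set(feature.index)
        if undefined:
            raise ValidationError(
                f"feature undefined for {len(undefined)} background probe(s)"
            )
        feature = set(feature.index[feature.astype(bool)])
    else:
        feature = set(feature)

    a = len(selected & feature)
    b = len(selected - feature)
    c = len((background - selected) & feature)
    d = len((background - selected) - feature)
    infinite = False
    if b * c == 0:
        if a * d == 0:
            odds_ratio = float("nan") if (a == 0 and b == 0) else 0.0 if a == 0 else float("inf")
            infinite = not np.isfinite(odds_ratio) and odds_ratio > 0
        else:
            odds_ratio = float("inf")
            infinite = True
    else:
        odds_ratio = (a * d) / (b * c)
    N, K, n_draws = len(background), a + c, a + b
    p = float(stats.hypergeom.sf(a - 1, N, K, n_draws))
    p = min(max(p, _P_FLOOR), 1.0)
    return EnrichmentResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=float(odds_ratio),
        p_value=p,
        odds_ratio_infinite=bool(infinite),
    )


def island_z_comparison(ewas: pd.DataFrame, annotation: CpGAnnotation) -> dict:
    """Welch t test of EWAS Z statistics, island vs non-island probes."""
    island = annotation.island_probes()
    z = ewas["z"].dropna()
    z_island = z[z.index.isin(island)]
    z_non = z[~z.index.isin(island)]
    if len(z_island) < 2 or len(z_non) < 2:
        raise ValidationError("each island stratum needs >=2 probes with defined Z")
    res = stats.ttest_ind(z_island, z_non, equal_var=False)
    return {
        "mean_z_island": float(z_island.mean()),
        "mean_z_non_island": float(z_non.mean()),
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "n_island": int(len(z_island)),
        "n_non_island": int(len(z_non)),
    }


def mean_methylation_by_island(
    betas: BetaMatrix, samples: SampleTable, annotation: CpGAnnotation
) -> pd.DataFrame:
    """Mean beta per tissue × island-status stratum, with spread summaries."""
    island = annotation.island_probes()
    rows = []
    for tissue in sorted(set(samples.df["tissue"])):
        sub = samples.subset(tissue=tissue)
        X = betas.samples_matrix(sub)  # n × p
        mask = np.array([p in island for p in betas.probe_ids])
        for status, sel in (("island", mask), ("non_island", ~mask)):
            if not sel.any():
                raise ValidationError(f"no {status} probes in annotation")
            vals = X[:, sel].ravel()
            rows.append(
                {
                    "tissue": tissue,
                    "island_status": status,
                    "mean_beta": float(vals.mean()),
                    "median_beta": float(np.median(vals)),
                    "sd_beta": float(vals.std()),
                    "n_probes": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


def cpgs_near_gene(
    annotation: CpGAnnotation,
    gene: str,
    flank_bp: int = 1_000_000,
    gene_coords: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All probes within ``flank_bp`` of a gene's TSS, ordered by position.

    The TSS is located from ``gene_coords`` (columns gene, chromosome, tss)
    when supplied, otherwise inferred from probes annotated to the gene
    (position − distance_to_tss).
    """
    df = annotation.df
    if gene_coords is not None and gene in set(gene_coords["gene"]):
        row = gene_coords.loc[gene_coords["gene"] == gene].iloc[0]
        chrom, tss = str(row["chromosome"]), int(row["tss"])
    else:
        hits = df[df["nearest_gene"] == gene]
        if hits.empty:
            known = sorted(set(df["nearest_gene"]))
            near = difflib.get_close_matches(gene, known, n=5)
            raise ValidationError(
                f"gene {gene!r} not found in annotation; close matches: {near}"
            )
        first = hits.iloc[0]
        chrom = str(first["chromosome"])
        tss = int(first["position"] - first["distance_to_tss"])
    sel = df[
        (df["chromosome"] == chrom)
        & (df["position"] - tss).abs().le(flank_bp)
    ].copy()
    sel["distance_to_gene_tss"] = sel["position"] - tss
    sel["side"] = np.where(sel["distance_to_gene_tss"] < 0, "upstream", "downstream")
    return sel.sort_values("position").reset_index(drop=True)
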