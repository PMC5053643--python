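"""Sample-similarity analysis: correlation matrices, paired best-match
structure, and Ward/Pearson hierarchical clustering with multiscale
bootstrap support values.

Two feature spaces are used: probe-level log2 ratios (copy-number
similarity) and per-variant allele fractions with absent variants encoded
as 0 (mutational similarity). Clustering distance is 1 - Pearson r between
sample vectors with Ward linkage.

Cluster support follows the multiscale-bootstrap construction: features
are resampled with replacement at several resampling ratios r, the
per-clade recovery frequency BP_r is recorded, probit(BP_r) is regressed
on (sqrt(r), 1/sqrt(r)) by weighted least squares, and the approximately
unbiased support is AU = 1 - Phi(v - c) from the fitted signed distance v
and curvature c (BP at r = 1 is the plain bootstrap proportion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .core import MetaconcordError, VariantKey

__all__ = [
    "vaf_feature_matrix",
    "cna_feature_matrix",
    "correlation_matrix",
    "best_match_assignment",
    "ward_pearson_cluster",
    "Dendrogram",
    "dendrogram_clades",
    "au_pvalues",
    "to_newick",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))


def vaf_feature_matrix(
    variants_by_sample: dict[str, pd.DataFrame], sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Samples x variant-keys matrix of allele fractions; an undetected
    variant is 0 (not missing), matching the all-detected-variants pooling."""
    if sample_ids is None:
        sample_ids = list(variants_by_sample)
    keys: dict[VariantKey, None] = {}
    for sid in sample_ids:
        t = variants_by_sample[sid]
        for r in t.itertuples(index=False):
            keys.setdefault(VariantKey(r.gene, r.chrom, int(r.pos), r.ref, r.alt))
    cols = list(keys)
    mat = np.zeros((len(sample_ids), len(cols)))
    index = {k: j for j, k in enumerate(cols)}
    for i, sid in enumerate(sample_ids):
        for r in variants_by_sample[sid].itertuples(index=False):
            mat[i, index[VariantKey(r.gene, r.chrom, int(r.pos), r.ref, r.alt)]] = r.vaf
    return pd.DataFrame(mat, index=sample_ids, columns=[str(k) for k in cols])


def cna_feature_matrix(
    profiles: dict[str, "object"], sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Samples x probes matrix of log2 ratios; probe sets must agree."""
    if sample_ids is None:
        sample_ids = list(profiles)
    ref = profiles[sample_ids[0]].probes["probe_id"].tolist()
    rows = []
    for sid in sample_ids:
        p = profiles[sid].probes
        if p["probe_id"].tolist() != ref:
            raise MetaconcordError(f"sample {sid}: probe set differs from {sample_ids[0]}")
        rows.append(p["log2ratio"].to_numpy())
    return pd.DataFrame(np.vstack(rows), index=sample_ids, columns=ref)


def _row_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of a and every row of b; zero-variance
    rows yield NaN entries (explicitly undefined, not propagated)."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((ac**2).sum(axis=1))
    nb = np.sqrt((bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(na, nb)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r, where=np.isfinite(r))


def correlation_matrix(
    primaries: pd.DataFrame, metastases: pd.DataFrame
) -> pd.DataFrame:
    """Metastasis x primary matrix of Pearson correlations over the shared
    feature set."""
    if list(primaries.columns) != list(metastases.columns):
        raise MetaconcordError("primary and metastasis matrices must share columns")
    if primaries.shape[1] < 2:
        raise MetaconcordError("need at least two features")
    r = _row_correlations(metastases.to_numpy(float), primaries.to_numpy(float))
    return pd.DataFrame(r, index=metastases.index, columns=primaries.index)


def best_match_assignment(
    matrix: pd.DataFrame, expected: dict[str, str] | None = None
) -> tuple[pd.DataFrame, float | None]:
    """Per-metastasis argmax primary; ties broken by lexicographic sample
    id and reported. When ``expected`` maps metastasis id to its true
    primary, the fraction correctly matched is returned too."""
    if matrix.empty:
        raise MetaconcordError("empty correlation matrix")
    rows = []
    for met, row in matrix.iterrows():
        vals = row.to_numpy(float)
        best = np.nanmax(vals)
        winners = sorted(matrix.columns[np.where(vals == best)[0]])
        rows.append(
            {
                "metastasis": met,
                "best_primary": winners[0],
                "correlation": float(best),
                "tie": len(winners) > 1,
            }
        )
    table = pd.DataFrame(rows)
    fraction = None
    if expected is not None:
        correct = [
            r.best_primary == expected[r.metastasis] for r in table.itertuples()
        ]
        fraction = float(np.mean(correct))
    return table, fraction


@dataclass
class Dendrogram:
    """A Ward dendrogram plus (optional) per-node bootstrap support."""

    linkage: np.ndarray
    labels: list[str]
    support: pd.DataFrame | None = None


def _pearson_condensed(samples: pd.DataFrame) -> np.ndarray:
    x = samples.to_numpy(float)
    sd = x.std(axis=1)
    for sid, s in zip(samples.index, sd):
        if s == 0:
            raise MetaconcordError(f"zero-variance sample vector: {sid}")
    r = _row_correlations(x, x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def ward_pearson_cluster(samples: pd.DataFrame) -> Dendrogram:
    """Ward linkage on 1 - Pearson distances between sample vectors."""
    if len(samples) < 2:
        raise MetaconcordError("need at least two samples to cluster")
    z = hierarchy.linkage(_pearson_condensed(samples), method="ward")
    return Dendrogram(linkage=z, labels=list(samples.index))


def dendrogram_clades(linkage: np.ndarray, labels: list[str]) -> list[frozenset]:
    """Leaf-label set of every internal node, in linkage-row order."""
    n = len(labels)
    clades: list[frozenset] = []
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    for row_idx, (a, b, *_rest) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        clades.append(merged)
    return clades


def sibling_pair_count(dendrogram: Dendrogram, pairs: list[tuple[str, str]]) -> int:
    """How many (primary, metastasis) pairs merge as sibling leaves."""
    clades = dendrogram_clades(dendrogram.linkage, dendrogram.labels)
    clade_set = set(clades)
    return sum(1 for a, b in pairs if frozenset([a, b]) in clade_set)


def _bootstrap_counts(
    samples: pd.DataFrame,
    original_clades: list[frozenset],
    scales: tuple[float, ...],
    n_boot_per_scale: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recovery counts (n_clades x n_scales) from feature resampling."""
    x = samples.to_numpy(float)
    labels = list(samples.index)
    n_features = x.shape[1]
    counts = np.zeros((len(original_clades), len(scales)), dtype=int)
    clade_index = {c: i for i, c in enumerate(original_clades)}
    for si, r in enumerate(scales):
        m = max(2, int(np.ceil(r * n_features)))
        for _ in range(n_boot_per_scale):
            cols = rng.integers(0, n_features, size=m)
            xb = x[:, cols]
            corr = _row_correlations(xb, xb)
            corr = np.nan_to_num(corr, nan=0.0)  # constant rows: distance 1
            d = 1.0 - corr
            np.fill_diagonal(d, 0.0)
            z = hierarchy.linkage(squareform(d, checks=False), method="ward")
            for clade in dendrogram_clades(z, labels):
                idx = clade_index.get(clade)
                if idx is not None:
                    counts[idx, si] += 1
    return counts


def _fit_au(
    bp: np.ndarray, scales: np.ndarray, n_boot: int
) -> tuple[float, float, float, bool]:
    """Fit the multiscale model for one clade.

    probit(BP_r) = v / sqrt(r) + c * sqrt(r) by weighted least squares;
    returns (au, v, c, degenerate). AU = 1 - Phi(v - c).
    """
    if np.all(bp >= 1.0):
        return 1.0, -np.inf, 0.0, True
    if np.all(bp <= 0.0):
        return 0.0, np.inf, 0.0, True
    eps = 1.0 / (2.0 * n_boot)
    bpc = np.clip(bp, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bpc)
    sigma = 1.0 / np.sqrt(scales)
    design = np.column_stack([sigma, 1.0 / sigma])  # [v, c]
    # binomial weights as in the reference multiscale-bootstrap fit
    w = n_boot * norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], z * sw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = float(1.0 - norm.cdf(v - c))
    return au, v, c, False


def au_pvalues(
    samples: pd.DataFrame,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_boot_per_scale: int = 100,
    random_state: int | np.random.Generator = 0,
) -> Dendrogram:
    """Ward/Pearson dendrogram with BP and AU support per internal node.

    ``bp`` is the plain bootstrap proportion at the resampling ratio
    closest to 1; ``au`` comes from the multiscale fit. Clades never (or
    always) recovered at every scale get AU 0 (or 1) with a degenerate-fit
    flag.
    """
    scales_arr = np.asarray(scales, dtype=float)
    if len(scales_arr) < 3 or scales_arr.min() >= 1 or scales_arr.max() <= 1:
        raise MetaconcordError(
            "need >= 3 resampling ratios spanning values below and above 1"
        )
    rng = (
        random_state
        if isinstance(random_state, np.random.Generator)
        else np.random.default_rng(random_state)
    )
    dend = ward_pearson_cluster(samples)
    clades = dendrogram_clades(dend.linkage, dend.labels)
    counts = _bootstrap_counts(samples, clades, tuple(scales_arr), n_boot_per_scale, rng)
    bp_all = counts / n_boot_per_scale
    at_one = int(np.argmin(np.abs(scales_arr - 1.0)))
    rows = []
    for i, clade in enumerate(clades):
        au, v, c, degenerate = _fit_au(bp_all[i], scales_arr, n_boot_per_scale)
        rows.append(
            {
                "node": i,
                "members": clade,
                "n_members": len(clade),
                "bp": float(bp_all[i, at_one]),
                "au": min(max(au, 0.0), 1.0),
                "v": v,
                "c": c,
                "degenerate_fit": degenerate,
            }
        )
    dend.support = pd.DataFrame(rows)
    return dend


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string; internal node labels carry AU/BP when available."""
    z = dendrogram.linkage
    labels = dendrogram.labels
    n = len(labels)
    support = {}
    if dendrogram.support is not None:
        support = {int(r.node): (r.au, r.bp) for r in dendrogram.support.itertuples()}

    def node_str(idx: int) -> str:
        if idx < n:
            return labels[idx].replace(" ", "_")
        row = idx - n
        a, b, height, _ = z[row]
        label = ""
        if row in support:
            au, bp = support[row]
            label = f"au{au:.2f}_bp{bp:.2f}"
        return f"({node_str(int(a))},{node_str(int(b))}){label}:{height:.6g}"

    return node_str(n + len(z) - 1) + ";"


def plot_correlation_heatmap(matrix: pd.DataFrame, path) -> None:
    """Correlation-matrix heatmap (metastases x primaries)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(float), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=5)
    ax.set_xlabel("primary tumors")
    ax.set_ylabel("metastases")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
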