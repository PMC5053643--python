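"""Copy-number analysis: segmentation, calling, and cohort statistics.

The probe-level log2-ratio profile of each sample is segmented with a
circular-binary-segmentation scheme: the change-point statistic is the
two-sample t between the interior and exterior of a circular arc, the best
arc is accepted when its within-segment permutation p-value falls below
``alpha``, and the accepted pieces are segmented recursively. Segments
shorter than ``min_probes`` (default five consecutive probes) are merged
into the neighbor with the closer mean, and every probe inherits its
segment mean as its *smoothed* value.

Calls use two symmetric thresholds on the smoothed value: |log2| > 0.5
separates gain/loss from neutral, |log2| > 1 separates high-level
amplification/deletion from gain/loss. Boundary convention (documented so
boundary tests are unambiguous): strict inequality at the outer boundary,
so mean > 1.0 is amplification and mean = 1.0 is a gain; symmetrically for
deletions.

Cohort-level statistics: the fraction of altered probes per sample, a
per-probe Fisher comparison of alteration frequencies between two groups,
gene-level amplification status and its pairwise concordance, and a
GISTIC-like frequency-times-amplitude scan with within-sample circular
permutation nulls and Benjamini-Hochberg q-values (regions with q < 0.25
reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ConfigurationError, MetaconcordError, ProbeProfile, SamplePair

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "CnaCall",
    "GeneRegion",
    "GisticRegion",
    "segment_profile",
    "smoothed_values",
    "call_cna",
    "probe_states",
    "fraction_altered",
    "gene_amplification_status",
    "pairwise_status_concordance",
    "locus_frequency_comparison",
    "gistic_like_scan",
]

STATE_CODES = {"deletion": -2, "loss": -1, "neutral": 0, "gain": 1, "amplification": 2}


@dataclass
class Segment:
    chrom: str
    start_index: int  # inclusive probe index within the chromosome
    end_index: int  # inclusive
    start_pos: int
    end_pos: int
    n_probes: int
    mean_log2: float


@dataclass
class CnaCall:
    segment: Segment
    state: str  # deletion | loss | neutral | gain | amplification


@dataclass
class GeneRegion:
    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(f"gene {self.gene}: start > end")


@dataclass
class GisticRegion:
    chrom: str
    start_pos: int
    end_pos: int
    direction: str  # amplified | deleted
    g_score: float
    p_value: float
    q_value: float


# ---------------------------------------------------------------------------
# segmentation


class _ArcCache:
    """Per-length auxiliary arrays for the arc t-statistic (reused across
    the many permutations evaluated at one stretch length)."""

    _store: dict[int, "_ArcCache"] = {}

    def __init__(self, n: int) -> None:
        jj = np.arange(n)[None, :]
        ii = np.arange(n)[:, None]
        k = jj - ii + 1
        self.valid = (k >= 1) & (k <= n - 1)
        k = np.where(self.valid, k, 1)
        m = n - k
        self.inv_k = 1.0 / k
        self.inv_m = 1.0 / m
        self.factor = self.inv_k + self.inv_m
        self.n = n

    @classmethod
    def get(cls, n: int) -> "_ArcCache":
        if n not in cls._store:
            if len(cls._store) > 64:  # keep the cache bounded
                cls._store.clear()
            cls._store[n] = cls(n)
        return cls._store[n]


def _arc_t_matrix(x: np.ndarray, cache: _ArcCache) -> np.ndarray:
    """|t| for every arc interior x[i..j] (rows i, cols j); invalid arcs
    are -inf. Infinite |t| (zero pooled variance, nonzero mean difference)
    is allowed and wins, which is what makes noiseless steps exactly
    recoverable."""
    n = cache.n
    S = np.concatenate([[0.0], np.cumsum(x)])
    total = S[-1]
    tt = float(x @ x)
    sum_in = S[1:][None, :] - S[:-1][:, None]
    sum_out = total - sum_in
    diff = np.abs(sum_in * cache.inv_k - sum_out * cache.inv_m)
    sse = tt - sum_in**2 * cache.inv_k - sum_out**2 * cache.inv_m
    np.maximum(sse, 0.0, out=sse)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(sse * (cache.factor / max(n - 2, 1)))
        t = diff / denom
    t[denom == 0.0] = np.where(diff[denom == 0.0] > 0.0, np.inf, 0.0)
    t[~cache.valid] = -np.inf
    return t


def _max_arc_t(x: np.ndarray) -> tuple[float, int, int]:
    """Maximum |t| over all circular arcs of ``x``.

    Arcs are the interiors x[i..j] (inclusive) with 1 <= length <= n-1;
    complements that wrap the boundary are covered by the complementary
    (i, j). Returns (|t|max, i, j) with the first maximizer in row-major
    order."""
    n = len(x)
    t = _arc_t_matrix(np.asarray(x, dtype=float), _ArcCache.get(n))
    flat = int(np.argmax(t))
    i, j = divmod(flat, n)
    return float(t[i, j]), i, j


def _split_accepted(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[bool, int, int]:
    """Permutation acceptance of the best arc split, with early stopping
    once the exceedance count guarantees p >= alpha."""
    t_obs, i, j = _max_arc_t(x)
    cache = _ArcCache.get(len(x))
    limit = max(1, int(np.ceil(alpha * n_perm)))
    exceed = 0
    for _ in range(n_perm):
        t_b = np.max(_arc_t_matrix(rng.permutation(x), cache))
        if t_b >= t_obs:
            exceed += 1
            if exceed >= limit:
                return False, i, j
    return (exceed / n_perm) < alpha, i, j


def _segment_indices(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Recursive CBS over a linear stretch; returns inclusive index pairs."""
    n = len(x)
    if n < 4:
        return [(0, n - 1)]
    accepted, i, j = _split_accepted(x, alpha, n_perm, rng)
    if not accepted:
        return [(0, n - 1)]
    pieces = []
    if i > 0:
        pieces.append((0, i - 1))
    pieces.append((i, j))
    if j < n - 1:
        pieces.append((j + 1, n - 1))
    if len(pieces) == 1:  # degenerate: arc is the whole stretch
        return [(0, n - 1)]
    out: list[tuple[int, int]] = []
    for lo, hi in pieces:
        sub = _segment_indices(x[lo : hi + 1], alpha, n_perm, rng)
        out.extend([(lo + a, lo + b) for a, b in sub])
    return out


def _merge_short(
    bounds: list[tuple[int, int]], x: np.ndarray, min_probes: int
) -> list[tuple[int, int]]:
    """Merge segments with fewer than ``min_probes`` probes into the
    neighbor with the closer mean."""
    bounds = sorted(bounds)
    while len(bounds) > 1:
        sizes = [b - a + 1 for a, b in bounds]
        short = [idx for idx, s in enumerate(sizes) if s < min_probes]
        if not short:
            break
        idx = min(short, key=lambda k: sizes[k])
        a, b = bounds[idx]
        mean = x[a : b + 1].mean()
        candidates = []
        if idx > 0:
            la, lb = bounds[idx - 1]
            candidates.append((abs(x[la : lb + 1].mean() - mean), idx - 1))
        if idx < len(bounds) - 1:
            ra, rb = bounds[idx + 1]
            candidates.append((abs(x[ra : rb + 1].mean() - mean), idx + 1))
        _, nb = min(candidates)
        lo = min(bounds[idx][0], bounds[nb][0])
        hi = max(bounds[idx][1], bounds[nb][1])
        bounds[min(idx, nb)] = (lo, hi)
        del bounds[max(idx, nb)]
    return bounds


def segment_profile(
    profile: ProbeProfile,
    alpha: float = 0.01,
    min_probes: int = 5,
    n_perm: int = 1000,
    random_state: int | np.random.Generator = 0,
) -> list[Segment]:
    """Segment a probe profile chromosome by chromosome.

    Raises if any chromosome carries fewer than ``min_probes`` probes.
    Probes are tiled exactly once and each segment's mean is the arithmetic
    mean of its member probes.
    """
    rng = (
        random_state
        if isinstance(random_state, np.random.Generator)
        else np.random.default_rng(random_state)
    )
    segments: list[Segment] = []
    for chrom in profile.chromosomes:
        x = profile.chrom_values(chrom)
        pos = profile.chrom_positions(chrom)
        if len(x) < min_probes:
            raise MetaconcordError(
                f"chromosome {chrom} has {len(x)} probes, fewer than min_probes={min_probes}"
            )
        bounds = _segment_indices(x, alpha, n_perm, rng)
        bounds = _merge_short(bounds, x, min_probes)
        for a, b in bounds:
            segments.append(
                Segment(
                    chrom=chrom,
                    start_index=a,
                    end_index=b,
                    start_pos=int(pos[a]),
                    end_pos=int(pos[b]),
                    n_probes=b - a + 1,
                    mean_log2=float(x[a : b + 1].mean()),
                )
            )
    return segments


def smoothed_values(profile: ProbeProfile, segments: list[Segment]) -> np.ndarray:
    """Per-probe smoothed value (its segment's mean), aligned with
    ``profile.probes`` row order."""
    out = np.empty(profile.n_probes)
    out.fill(np.nan)
    offset = 0
    for chrom in profile.chromosomes:
        n = int((profile.probes["chrom"] == chrom).sum())
        for seg in segments:
            if seg.chrom == chrom:
                out[offset + seg.start_index : offset + seg.end_index + 1] = seg.mean_log2
        offset += n
    if np.isnan(out).any():
        raise MetaconcordError("segments do not tile the profile")
    return out


# ---------------------------------------------------------------------------
# calling


def call_cna(
    segments: list[Segment], low_thr: float = 0.5, high_thr: float = 1.0
) -> list[CnaCall]:
    """Two-threshold state calling on segment means.

    amplification: mean > high_thr; gain: low_thr < mean <= high_thr;
    deletion: mean < -high_thr; loss: -high_thr <= mean < -low_thr;
    neutral otherwise.
    """
    if not 0 < low_thr < high_thr:
        raise ConfigurationError(
            f"thresholds must satisfy 0 < low_thr < high_thr, got {low_thr}, {high_thr}"
        )
    calls = []
    for seg in segments:
        m = seg.mean_log2
        if m > high_thr:
            state = "amplification"
        elif m > low_thr:
            state = "gain"
        elif m < -high_thr:
            state = "deletion"
        elif m < -low_thr:
            state = "loss"
        else:
            state = "neutral"
        calls.append(CnaCall(segment=seg, state=state))
    return calls


def probe_states(profile: ProbeProfile, calls: list[CnaCall]) -> np.ndarray:
    """Integer state code per probe (-2 del .. +2 amp), aligned with the
    profile's probe order."""
    out = np.zeros(profile.n_probes, dtype=int)
    offset = 0
    for chrom in profile.chromosomes:
        n = int((profile.probes["chrom"] == chrom).sum())
        for c in calls:
            if c.segment.chrom == chrom:
                out[offset + c.segment.start_index : offset + c.segment.end_index + 1] = (
                    STATE_CODES[c.state]
                )
        offset += n
    return out


def fraction_altered(calls: list[CnaCall], total_probes: int) -> float:
    """Fraction of probes lying in non-neutral segments."""
    if total_probes <= 0:
        raise ConfigurationError("total_probes must be > 0")
    altered = sum(c.segment.n_probes for c in calls if c.state != "neutral")
    return altered / total_probes


def gene_amplification_status(calls: list[CnaCall], region: GeneRegion) -> str:
    """'amplified' iff any probe overlapping the gene region lies in an
    amplification-state segment."""
    chroms = {c.segment.chrom for c in calls}
    if region.chrom not in chroms:
        raise MetaconcordError(
            f"chromosome {region.chrom} for gene {region.gene} absent from calls"
        )
    for c in calls:
        if c.state != "amplification" or c.segment.chrom != region.chrom:
            continue
        if c.segment.start_pos <= region.end and c.segment.end_pos >= region.start:
            return "amplified"
    return "non_amplified"


def pairwise_status_concordance(
    calls_by_sample: dict[str, list[CnaCall]],
    pairs: list[SamplePair],
    region: GeneRegion,
) -> tuple[float, pd.DataFrame]:
    """Per-pair amplified/non-amplified agreement for one gene region."""
    rows = []
    for p in pairs:
        for role, sid in (("primary", p.primary_sample), ("metastasis", p.metastasis_sample)):
            if sid not in calls_by_sample:
                raise MetaconcordError(
                    f"patient {p.patient_id}: missing {role} sample {sid}"
                )
        sp = gene_amplification_status(calls_by_sample[p.primary_sample], region)
        sm = gene_amplification_status(calls_by_sample[p.metastasis_sample], region)
        rows.append(
            {
                "patient_id": p.patient_id,
                "gene": region.gene,
                "primary_status": sp,
                "metastasis_status": sm,
                "concordant": sp == sm,
            }
        )
    table = pd.DataFrame(rows)
    rate = float(table["concordant"].mean()) if len(table) else float("nan")
    return rate, table


# ---------------------------------------------------------------------------
# per-locus group comparison


def locus_frequency_comparison(
    states_a: np.ndarray, states_b: np.ndarray
) -> pd.DataFrame:
    """Per-probe two-sided Fisher tests of alteration frequency between two
    sample groups.

    ``states_a``/``states_b`` are (samples x probes) integer state-code
    matrices. Gain/amplification (codes > 0) and loss/deletion (codes < 0)
    are tested separately; returns per-probe p-values and -log10 tracks.
    """
    states_a = np.atleast_2d(states_a)
    states_b = np.atleast_2d(states_b)
    if states_a.size == 0 or states_b.size == 0:
        raise MetaconcordError("both groups must be non-empty")
    if states_a.shape[1] != states_b.shape[1]:
        raise MetaconcordError("probe dimensions differ between groups")
    na, nb = states_a.shape[0], states_b.shape[0]
    out = {"p_gain": [], "p_loss": []}
    for sign, col in ((1, "p_gain"), (-1, "p_loss")):
        alt_a = (sign * states_a > 0).sum(axis=0)
        alt_b = (sign * states_b > 0).sum(axis=0)
        for ka, kb in zip(alt_a, alt_b):
            _, p = stats.fisher_exact([[ka, na - ka], [kb, nb - kb]])
            out[col].append(p)
    df = pd.DataFrame(out)
    df["neglog10_p_gain"] = -np.log10(df["p_gain"])
    df["neglog10_p_loss"] = -np.log10(df["p_loss"])
    return df


# ---------------------------------------------------------------------------
# GISTIC-like scan


def gistic_like_scan(
    smoothed: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    direction: str = "amplified",
    n_resample: int = 1000,
    q_threshold: float = 0.25,
    low_thr: float = 0.5,
    random_state: int | np.random.Generator = 0,
) -> tuple[list[GisticRegion], pd.DataFrame]:
    """Frequency-times-amplitude scan for recurrently altered regions.

    Per-probe G-score = sum over samples of the smoothed value's excursion
    beyond ``low_thr`` in the requested direction. The null distribution is
    built by within-sample circular permutation of probe positions
    (``n_resample`` draws, pooled across probes); per-probe p-values get
    Benjamini-Hochberg q-values, and maximal runs of contiguous probes with
    q below ``q_threshold`` are reported as regions.
    """
    smoothed = np.atleast_2d(np.asarray(smoothed, dtype=float))
    n_samples, n_probes = smoothed.shape
    if n_samples == 0:
        raise MetaconcordError("gistic_like_scan requires at least one sample")
    if n_samples < 2:
        raise MetaconcordError("gistic_like_scan requires >= 2 samples")
    if n_resample < 100:
        logger.warning("n_resample=%d is low; q-values will be unstable", n_resample)
    if direction not in ("amplified", "deleted"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    rng = (
        random_state
        if isinstance(random_state, np.random.Generator)
        else np.random.default_rng(random_state)
    )
    sign = 1.0 if direction == "amplified" else -1.0
    excess = np.maximum(0.0, sign * smoothed - low_thr)  # (samples, probes)
    g_obs = excess.sum(axis=0)
    null_pool = np.empty(n_resample * n_probes)
    for b in range(n_resample):
        g_null = np.zeros(n_probes)
        offsets = rng.integers(0, n_probes, size=n_samples)
        for s in range(n_samples):
            g_null += np.roll(excess[s], int(offsets[s]))
        null_pool[b * n_probes : (b + 1) * n_probes] = g_null
    null_pool.sort()
    # p = fraction of pooled null scores >= observed (add-one to avoid 0)
    ge = len(null_pool) - np.searchsorted(null_pool, g_obs, side="left")
    p = (ge + 1.0) / (len(null_pool) + 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    track = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "g_score": g_obs, "p_value": p, "q_value": q}
    )
    regions: list[GisticRegion] = []
    sig = q < q_threshold
    i = 0
    while i < n_probes:
        if sig[i]:
            j = i
            while j + 1 < n_probes and sig[j + 1] and chroms[j + 1] == chroms[i]:
                j += 1
            regions.append(
                GisticRegion(
                    chrom=str(chroms[i]),
                    start_pos=int(positions[i]),
                    end_pos=int(positions[j]),
                    direction=direction,
                    g_score=float(g_obs[i : j + 1].max()),
                    p_value=float(p[i : j + 1].min()),
                    q_value=float(q[i : j + 1].min()),
                )
            )
            i = j + 1
        else:
            i += 1
    return regions, track
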