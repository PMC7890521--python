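"""Representational similarity analysis: RDMs, correspondence, partial correlation.

The dissimilarity between the population responses to two stimuli is the
correlation distance

    RD(i, j) = 1 - corr(pattern_i, pattern_j),

where a *pattern* is the vector of unit responses (neurons of one area, or
all model neurons from all channels of one network layer) to a stimulus and
the subtracted means are the across-unit means per stimulus.  RD ranges
over [0, 2]: 0 for identical patterns, 2 for exactly anti-correlated ones.
The n(n-1)/2 off-diagonal values (2016 for the 64-stimulus design) may be
summarised as percentiles (average ranks scaled to (0, 1]).

Two RDMs are compared by the *correspondence* r_vl — the Pearson
correlation of their off-diagonal upper triangles — and, to isolate the
contribution of a single cortical area, by the first-order partial
correlation

    r_lx.y = (r_lx - r_xy r_ly) / sqrt((1 - r_xy^2)(1 - r_ly^2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RDM",
    "DegenerateDataError",
    "UndefinedResult",
    "compute_rdm",
    "percentile_transform",
    "correspondence",
    "partial_correlation",
    "partial_correlation_profile",
    "per_channel_correspondence",
    "channel_histogram",
    "profile_over_models",
    "RDMTransform",
    "upper_triangle",
]


class DegenerateDataError(ValueError):
    """A constant pattern (or zero-variance triangle) makes a value undefined."""


@dataclass
class UndefinedResult:
    """Flag object standing in for an undefined correlation value."""

    reason: str

    def __float__(self):
        return float("nan")


@dataclass
class RDM:
    """Symmetric dissimilarity matrix with zero diagonal.

    ``form`` is "raw" (correlation distances in [0, 2]) or "percentile"
    (rank-summarised to (0, 1]); ``source`` labels the area or layer.
    """

    matrix: np.ndarray
    form: str = "raw"
    source: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("RDM diagonal must be zero")
        if self.form == "raw" and (m.min() < -1e-10 or m.max() > 2 + 1e-10):
            raise ValueError("raw RDM entries must lie in [0, 2]")
        if self.form == "percentile" and (m.min() < 0 or m.max() > 1 + 1e-12):
            raise ValueError("percentile RDM entries must lie in [0, 1]")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """The n(n-1)/2 off-diagonal upper-triangle values, row-major."""
    m = np.asarray(matrix)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _as_matrix(rdm) -> np.ndarray:
    return rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, float)


def compute_rdm(patterns, source: str = "", drop_degenerate: bool = False) -> RDM:
    """Correlation-distance RDM of a (stimuli x units) pattern matrix.

    Accepts a plain array, a DataFrame, or a RateTable-like object with a
    ``values`` attribute.  Each stimulus pattern is correlated with every
    other across units; ``RD = 1 - r``.  A constant pattern has no defined
    correlation: by default this raises naming the stimulus, or with
    ``drop_degenerate`` the offending stimuli are removed (never silently
    propagated as NaN, which would corrupt percentile ranks downstream).
    """
    if hasattr(patterns, "values") and not isinstance(patterns, np.ndarray):
        X = np.asarray(patterns.values, dtype=np.float64)
    else:
        X = np.asarray(patterns, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("patterns must be a (stimuli, units) matrix")
    if X.shape[1] < 2:
        raise ValueError("need >= 2 units per pattern")
    sd = X.std(axis=1)
    degenerate = np.where(sd == 0)[0]
    if degenerate.size:
        if not drop_degenerate:
            raise DegenerateDataError(
                f"constant pattern for stimulus index/indices "
                f"{degenerate.tolist()}: correlation distance undefined")
        X = np.delete(X, degenerate, axis=0)
        if X.shape[0] < 2:
            raise DegenerateDataError("fewer than 2 non-constant patterns")
    with np.errstate(invalid="raise"):
        corr = np.corrcoef(X)
    rd = 1.0 - corr
    # snap float dust at the anchors: identical patterns -> exactly 0,
    # exactly anti-correlated -> exactly 2
    rd[np.abs(rd) < 1e-12] = 0.0
    rd[np.abs(rd - 2.0) < 1e-12] = 2.0
    rd = np.clip(rd, 0.0, 2.0)
    rd = (rd + rd.T) / 2.0
    np.fill_diagonal(rd, 0.0)
    return RDM(matrix=rd, form="raw", source=source)


def percentile_transform(rdm: RDM) -> RDM:
    """Summarise a raw RDM's off-diagonal values as percentiles.

    The n(n-1)/2 upper-triangle values are rank-transformed (average ranks
    on ties) and scaled to (0, 1]; the result is mirrored to keep symmetry
    and the diagonal stays zero.  Any strictly monotone rescale leaves the
    subsequent Pearson correspondence unchanged on tie-free data; ranks
    make it exactly Spearman's correlation on the raw values.
    """
    if isinstance(rdm, RDM):
        if rdm.form != "raw":
            raise ValueError("percentile_transform expects a raw-form RDM")
        m, source = rdm.matrix, rdm.source
    else:
        m, source = np.asarray(rdm, float), ""
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(m[iu], method="average")
    pct = ranks / ranks.size
    out = np.zeros_like(m)
    out[iu] = pct
    out = out + out.T
    return RDM(matrix=out, form="percentile", source=source)


def correspondence(rdm_a, rdm_b) -> float:
    """Pearson correlation between two RDMs' off-diagonal upper triangles.

    Diagonal elements (identically zero) are excluded.  Both RDMs must have
    the same size and, when given as :class:`RDM`, the same form.  Zero
    variance in either triangle leaves the value undefined and raises
    :class:`DegenerateDataError`.
    """
    if isinstance(rdm_a, RDM) and isinstance(rdm_b, RDM):
        if rdm_a.form != rdm_b.form:
            raise ValueError(
                f"RDM forms differ: {rdm_a.form!r} vs {rdm_b.form!r}")
    a = upper_triangle(_as_matrix(rdm_a))
    b = upper_triangle(_as_matrix(rdm_b))
    if a.shape != b.shape:
        raise ValueError("RDM sizes differ")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateDataError("zero variance in an RDM triangle; "
                                  "correspondence undefined")
    return float(stats.pearsonr(a, b).statistic)


def partial_correlation(r_lx: float, r_xy: float, r_ly: float):
    """First-order partial correlation r_lx.y.

    Removes the linear contribution of structure y from the layer-area
    correlation r_lx.  Undefined when |r_xy| = 1 or |r_ly| = 1 (zero
    denominator); that case returns an :class:`UndefinedResult` flag rather
    than raising, so batch reports can carry it as a flagged null.
    """
    for name, r in (("r_lx", r_lx), ("r_xy", r_xy), ("r_ly", r_ly)):
        if not -1 <= r <= 1:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    denom = np.sqrt((1.0 - r_xy ** 2) * (1.0 - r_ly ** 2))
    if denom == 0:
        return UndefinedResult(reason="|r_xy| or |r_ly| equals 1")
    return float((r_lx - r_xy * r_ly) / denom)


def partial_correlation_profile(layer_rdms: dict, area_rdms: dict) -> pd.DataFrame:
    """Batch partial correlations for every (layer, target area, removed area).

    ``layer_rdms`` maps layer_id -> RDM, ``area_rdms`` maps area -> RDM
    (same form).  Emits all ordered area pairs (x, y), x != y, per layer —
    six rows per layer for the three-area design — retaining the
    constituent correlations r_lx, r_xy, r_ly for audit.  Undefined results
    appear as NaN with ``defined = False``, never silently dropped.
    """
    areas = list(area_rdms)
    r_between = {(x, y): correspondence(area_rdms[x], area_rdms[y])
                 for x in areas for y in areas if x != y}
    rows = []
    for layer_id, lrdm in layer_rdms.items():
        r_l = {x: correspondence(lrdm, area_rdms[x]) for x in areas}
        for x in areas:
            for y in areas:
                if x == y:
                    continue
                val = partial_correlation(r_l[x], r_between[(x, y)], r_l[y])
                defined = not isinstance(val, UndefinedResult)
                rows.append({
                    "layer": layer_id, "area": x, "removed_area": y,
                    "r_partial": float(val) if defined else np.nan,
                    "r_lx": r_l[x], "r_xy": r_between[(x, y)],
                    "r_ly": r_l[y], "defined": defined,
                })
    return pd.DataFrame(rows)


def per_channel_correspondence(activations: np.ndarray, area_rdm,
                               form: str = "percentile") -> pd.DataFrame:
    """Correspondence between each single channel's RDM and an area RDM.

    ``activations`` is (stimuli, height, width, channels): the recorded
    activation tensors of one layer stacked over stimuli.  Each channel's
    model neurons form their own pattern set; channels with any constant
    pattern (e.g. silenced throughout by the ReLU) have no defined RDM and
    are excluded but tallied.  Returns a DataFrame
    (channel, r, excluded).
    """
    activations = np.asarray(activations, dtype=np.float64)
    if activations.ndim != 4:
        raise ValueError("activations must be (stimuli, H, W, channels)")
    n_stim, h, w, n_ch = activations.shape
    if isinstance(area_rdm, RDM) and form != area_rdm.form:
        raise ValueError("area RDM form does not match requested form")
    rows = []
    for c in range(n_ch):
        patterns = activations[:, :, :, c].reshape(n_stim, h * w)
        try:
            rdm = compute_rdm(patterns, source=f"channel{c}")
            if form == "percentile":
                rdm = percentile_transform(rdm)
            r = correspondence(rdm, area_rdm)
            rows.append({"channel": c, "r": r, "excluded": False})
        except DegenerateDataError:
            rows.append({"channel": c, "r": np.nan, "excluded": True})
    return pd.DataFrame(rows)


def channel_histogram(per_channel: pd.DataFrame, bins=20, value_range=(-1, 1)):
    """Frequency histogram of per-channel correspondences, normalised to the
    total channel count of the layer (excluded channels count toward the
    total, so bin fractions sum to the included fraction)."""
    r = per_channel.loc[~per_channel["excluded"], "r"].to_numpy()
    counts, edges = np.histogram(r, bins=bins, range=value_range)
    total = len(per_channel)
    return counts / total, edges


def profile_over_models(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean and SEM of correspondence over independently trained models.

    Each table has columns (layer, area, r) for one trained replicate; all
    replicates must cover the same (layer, area) grid.  SEM is sd/sqrt(m)
    over the m replicates (ddof=1); a single replicate reports SEM 0 with
    a warning.  Layer ordering follows the first table's recording-point
    sequence.
    """
    if not tables:
        raise ValueError("need >= 1 replicate table")
    key = ["layer", "area"]
    ref = tables[0][key].reset_index(drop=True)
    for t in tables[1:]:
        if not ref.equals(t[key].reset_index(drop=True)):
            raise ValueError("replicates cover different (layer, area) sets")
    m = len(tables)
    if m == 1:
        warnings.warn("single replicate: SEM reported as 0")
    stacked = np.stack([t["r"].to_numpy() for t in tables])
    out = ref.copy()
    out["mean_r"] = stacked.mean(axis=0)
    # shift by the first replicate before the std so identical replicates
    # yield an exact zero rather than float dust
    out["sem"] = ((stacked - stacked[0]).std(axis=0, ddof=1) / np.sqrt(m)) \
        if m > 1 else 0.0
    out["n_models"] = m
    return out


class RDMTransform(BaseEstimator, TransformerMixin):
    """Transformer computing a correlation-distance RDM from pattern matrices.

    ``transform(X)`` maps a (stimuli, units) matrix to its RDM matrix in
    the configured form ("raw" or "percentile").  Stateless (``fit`` is a
    no-op) so it slots into sklearn pipelines after unit standardisation.
    """

    def __init__(self, form: str = "percentile", drop_degenerate: bool = False):
        self.form = form
        self.drop_degenerate = drop_degenerate

    def fit(self, X, y=None):
        if self.form not in {"raw", "percentile"}:
            raise ValueError("form must be 'raw' or 'percentile'")
        return self

    def transform(self, X) -> np.ndarray:
        rdm = compute_rdm(X, drop_degenerate=self.drop_degenerate)
        if self.form == "percentile":
            rdm = percentile_transform(rdm)
        return rdm.matrix
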