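"""Rate-table I/O, responsiveness screening, and per-neuron standardisation.

A :class:`RateTable` is a stimuli x neurons matrix of mean firing rates
(spikes/s) for one cortical area (or a model layer / synthetic population).
Before a representational dissimilarity matrix is computed, neurons are
screened for visual responsiveness (Kruskal-Wallis across stimuli on
trial-level rates, p < 0.01) and each surviving neuron is standardised to
mean 0, variance 1 across the stimulus set.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "RateTable",
    "ZScoredTable",
    "FormatError",
    "load_rate_table",
    "save_rate_table",
    "responsiveness_screen",
    "zscore_per_neuron",
    "NeuronZScorer",
    "ResponsivenessScreen",
    "save_trials_h5",
    "load_trials_h5",
]


class FormatError(ValueError):
    """A rate-table file violates the TSV contract."""


@dataclass
class RateTable:
    """Stimuli x neurons response matrix for one area.

    ``rates`` is a DataFrame indexed by stimulus_id (ascending) with one
    column per neuron.  Requires >= 2 stimuli, >= 2 neurons, finite values.
    """

    rates: pd.DataFrame
    area: str = "synthetic"

    def __post_init__(self):
        df = self.rates
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValueError("RateTable needs >= 2 stimuli and >= 2 neurons")
        if df.isna().any().any():
            raise ValueError("RateTable contains missing entries")
        if not np.all(np.isfinite(df.to_numpy(dtype=float))):
            raise ValueError("RateTable contains non-finite rates")
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise ValueError("duplicate stimulus or neuron ids")
        self.rates = df.sort_index()

    @property
    def values(self) -> np.ndarray:
        return self.rates.to_numpy(dtype=float)

    @property
    def stimulus_ids(self) -> list:
        return list(self.rates.index)

    @property
    def neuron_ids(self) -> list:
        return list(self.rates.columns)

    @property
    def n_stimuli(self) -> int:
        return self.rates.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[1]


@dataclass
class ZScoredTable(RateTable):
    """A RateTable whose columns each have mean 0 and variance 1."""

    def __post_init__(self):
        super().__post_init__()
        v = self.values
        if not (np.allclose(v.mean(axis=0), 0, atol=1e-9)
                and np.allclose(v.var(axis=0), 1, atol=1e-9)):
            raise ValueError("columns must have mean 0 and variance 1")


def save_rate_table(table: RateTable, path) -> None:
    """Write TSV (rows = stimulus_ids, columns = neuron ids) + JSON sidecar."""
    # %.17g round-trips float64 exactly
    table.rates.to_csv(path, sep="\t", float_format="%.17g")
    Path(path).with_suffix(".json").write_text(
        json.dumps({"area": table.area, "n_stimuli": table.n_stimuli,
                    "n_neurons": table.n_neurons}))


def load_rate_table(path, area: str | None = None) -> RateTable:
    """Read a rate table written by :func:`save_rate_table`.

    Malformed files (blank cells, non-numeric entries, duplicate ids) raise
    :class:`FormatError` naming the offending row/column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise FormatError(
            f"{path}: missing or non-numeric cell at stimulus {row}, "
            f"neuron {col!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate stimulus_id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate neuron id {dup!r}")
    if area is None:
        sidecar = Path(path).with_suffix(".json")
        area = (json.loads(sidecar.read_text()).get("area", "unknown")
                if sidecar.exists() else "unknown")
    try:
        return RateTable(rates=numeric, area=area)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def save_trials_h5(trials: np.ndarray, path) -> None:
    """Store a stimuli x neurons x trials rate array in HDF5."""
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("trials", data=np.asarray(trials, dtype=float))
        d.attrs["axes"] = "stimuli,neurons,trials"


def load_trials_h5(path) -> np.ndarray:
    with h5py.File(path, "r") as fh:
        return fh["trials"][...]


def kruskal_wallis_by_neuron(trials: np.ndarray):
    """Kruskal-Wallis H and p per neuron, stimuli as groups.

    ``trials`` is (stimuli, neurons, trials).  The H statistic is the
    standard rank-based, tie-corrected one with a chi-square(k-1)
    approximation.  Neurons with identical rates everywhere get H = 0,
    p = 1 (no evidence of stimulus selectivity).
    """
    trials = np.asarray(trials, dtype=float)
    n_stim, n_neur, n_tr = trials.shape
    if n_stim < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 stimuli")
    if n_tr < 2:
        raise ValueError("need >= 2 trials per stimulus")
    H = np.empty(n_neur)
    p = np.empty(n_neur)
    for j in range(n_neur):
        groups = [trials[i, j, :] for i in range(n_stim)]
        flat = np.concatenate(groups)
        if np.all(flat == flat[0]):
            H[j], p[j] = 0.0, 1.0
            continue
        res = stats.kruskal(*groups)
        H[j], p[j] = res.statistic, res.pvalue
    return H, p


def responsiveness_screen(table: RateTable, trials: np.ndarray | None,
                          alpha: float = 0.01):
    """Keep neurons whose trial-level rates differ across stimuli.

    ``trials`` is a (stimuli, neurons, trials) array aligned with the
    table.  Returns ``(filtered RateTable, report DataFrame)`` where the
    report has one row per neuron (neuron_id, H, p, kept).  When no
    trial-level data exist the screen cannot run; it is skipped with a log
    message and every neuron kept.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if table.n_stimuli < 2:
        raise ValueError("screen needs >= 2 stimuli")
    if trials is None:
        logger.warning("no trial-level data: responsiveness screen skipped, "
                       "all %d neurons kept", table.n_neurons)
        report = pd.DataFrame({"neuron_id": table.neuron_ids,
                               "H": np.nan, "p": np.nan, "kept": True})
        return table, report
    trials = np.asarray(trials, dtype=float)
    if trials.shape[:2] != (table.n_stimuli, table.n_neurons):
        raise ValueError("trials array does not align with the rate table")
    H, p = kruskal_wallis_by_neuron(trials)
    kept = p < alpha
    report = pd.DataFrame({"neuron_id": table.neuron_ids, "H": H, "p": p,
                           "kept": kept})
    filtered = table.rates.loc[:, kept]
    if filtered.shape[1] < 2:
        raise ValueError(
            f"responsiveness screen kept {int(kept.sum())} neuron(s); "
            "need >= 2 for an RDM")
    return RateTable(rates=filtered, area=table.area), report


def zscore_per_neuron(table: RateTable, strict: bool = False,
                      ddof: int = 0) -> ZScoredTable:
    """Standardise each neuron to mean 0, variance 1 across stimuli.

    Uses the population (divide-by-n) variance by default.  Zero-variance
    neurons cannot be standardised: they are dropped with a warning unless
    ``strict`` is set, in which case they raise.
    """
    v = table.values
    sd = v.std(axis=0, ddof=ddof)
    dead = sd == 0
    if dead.any():
        names = [n for n, d in zip(table.neuron_ids, dead) if d]
        if strict:
            raise ValueError(f"zero-variance neuron(s): {names}")
        warnings.warn(f"dropping {len(names)} zero-variance neuron(s): "
                      f"{names[:5]}{'...' if len(names) > 5 else ''}")
        logger.warning("dropped %d zero-variance neurons", len(names))
    keep = ~dead
    if keep.sum() < 2:
        raise ValueError("fewer than 2 neurons with nonzero variance")
    z = (v[:, keep] - v[:, keep].mean(axis=0)) / sd[keep]
    df = pd.DataFrame(z, index=table.rates.index,
                      columns=[n for n, k in zip(table.neuron_ids, keep) if k])
    return ZScoredTable(rates=df, area=table.area)


class NeuronZScorer(BaseEstimator, TransformerMixin):
    """Transformer standardising each unit column to mean 0, variance 1.

    Operates on plain (stimuli, units) arrays so it composes with sklearn
    pipelines; ``ddof=0`` (population variance) matches
    :func:`zscore_per_neuron`.  Zero-variance columns are dropped (strict
    mode raises instead); indices of the kept columns are in ``kept_``.
    """

    def __init__(self, ddof: int = 0, strict: bool = False):
        self.ddof = ddof
        self.strict = strict

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=0, ddof=self.ddof)
        dead = sd == 0
        if dead.any() and self.strict:
            raise ValueError(f"zero-variance columns: {np.where(dead)[0]}")
        self.kept_ = np.where(~dead)[0]
        self.mean_ = X[:, self.kept_].mean(axis=0)
        self.scale_ = sd[self.kept_]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X[:, self.kept_] - self.mean_) / self.scale_


class ResponsivenessScreen(BaseEstimator, TransformerMixin):
    """Transformer form of the Kruskal-Wallis responsiveness screen.

    ``fit`` consumes a (stimuli, neurons, trials) array and selects the
    columns with p < alpha; ``transform`` filters any aligned
    (stimuli, neurons) matrix down to the kept columns.  Fitted attributes:
    ``H_``, ``pvalues_``, ``kept_``.
    """

    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def fit(self, X, y=None):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.H_, self.pvalues_ = kruskal_wallis_by_neuron(X)
        self.kept_ = np.where(self.pvalues_ < self.alpha)[0]
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.kept_]
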