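"""Null calibration of S*: simulate no-introgression data, model expected S*.

S* has no analytical null distribution, so significance is calibrated by
simulation: data are generated under a demographic model *without* gene flow
into the target, scored with the identical filtering/window/scan path as real
data, and a quantile surface ("expected S*") is fitted as a function of the
window's mutation count and local recombination rate. A window in real data
is flagged when its observed S* strictly exceeds the expected S* at the chosen
quantile.

The surface is fitted per quantile by computing empirical quantiles of
positive S* within covariate bins and smoothing them with B-spline regression
(weighted by bin occupancy; flexibility chosen by generalized
cross-validation). Windows with S* = 0 carry no chain signal and are excluded
from both fitting and flagging, so an exceedance rate of 1 - q applies to the
positive-score windows. Predictions are sorted across the quantile grid
pointwise, which enforces monotonicity in q by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from ._simtools import gene_flow_into, load_graph, matrix_from_ts, score_matrix, simulate_ts
from .genotype_io import PopulationAssignment
from .preprocess import RecombMap, Window, local_recomb_rate
from .sstar_core import ScoreFunctionParams

logger = logging.getLogger(__name__)

__all__ = [
    "simulate_null",
    "ExpectedScoreModel",
    "fit_expected_model",
    "call_outliers",
]

RATE_FLOOR = 1e-12  # recombination rates enter as log10(max(rate, floor))


def simulate_null(model, *, n_reps: int, seq_len: float, mu: float,
                  recomb_rate: float, samples: dict[str, int], ref_pop: str,
                  tgt_pop: str, seed: int, window_size: int = 50_000,
                  step: int = 10_000,
                  params: ScoreFunctionParams = ScoreFunctionParams(),
                  ref_max_daf: float = 0.0) -> pd.DataFrame:
    """Simulate and score independent no-introgression replicates.

    ``model`` is a demes graph / YAML path / YAML string. The graph must have
    no pulse or migration into ``tgt_pop`` — that would contaminate the null.
    Each replicate is a chromosome of ``seq_len`` bp scored exactly like real
    data. Returns one row per (replicate, window, target individual) with
    columns sstar, n_snps, recomb_rate, rep, sample. Deterministic given seed.
    """
    graph = load_graph(model)
    donors = gene_flow_into(graph, tgt_pop)
    if donors:
        raise ValueError(
            f"model has gene flow into target {tgt_pop!r} from {donors}; "
            "the null model must be introgression-free")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(1, 2**31 - 1, size=n_reps)
    frames = []
    for rep, rep_seed in enumerate(rep_seeds):
        ts = simulate_ts(graph, samples, seq_len, mu, recomb_rate,
                         int(rep_seed))
        gm, by_pop = matrix_from_ts(ts)
        assignment = PopulationAssignment(by_pop[ref_pop], by_pop[tgt_pop])
        scores, _ = score_matrix(gm, assignment, int(seq_len), window_size,
                                 step, params, ref_max_daf)
        scores = scores.rename(columns={"n_snps_window": "n_snps"})
        scores["recomb_rate"] = recomb_rate
        scores["rep"] = rep
        frames.append(scores[["sstar", "n_snps", "recomb_rate", "rep",
                              "sample"]])
    return pd.concat(frames, ignore_index=True)


class ExpectedScoreModel:
    """Fitted expected-S* quantile surface over (mutation count, recomb rate).

    The fitted surfaces are stored on a dense covariate grid and evaluated by
    (bi)linear interpolation, clamped to the training hull; this makes the
    model JSON-serializable and bit-identical on reload.
    """

    def __init__(self, q_grid, n_grid, logr_grid, surface, meta=None):
        self.q_grid = np.asarray(q_grid, dtype=float)
        self.n_grid = np.asarray(n_grid, dtype=float)
        self.logr_grid = np.asarray(logr_grid, dtype=float)
        self.surface = np.asarray(surface, dtype=float)
        self.meta = dict(meta or {})
        if self.surface.shape != (len(self.q_grid), len(self.n_grid),
                                  len(self.logr_grid)):
            raise ValueError("surface shape does not match grids")

    def _q_index(self, q: float) -> int:
        idx = np.flatnonzero(np.isclose(self.q_grid, q))
        if len(idx) == 0:
            raise ValueError(
                f"quantile {q} not in fitted grid {self.q_grid.tolist()}")
        return int(idx[0])

    def predict(self, n_snps, recomb_rate, q: float) -> np.ndarray:
        """Expected S* at quantile q; covariates clamped to the training hull."""
        qi = self._q_index(q)
        n = np.atleast_1d(np.asarray(n_snps, dtype=float))
        logr = np.log10(np.maximum(np.atleast_1d(
            np.asarray(recomb_rate, dtype=float)), RATE_FLOOR))
        n_out = (n < self.n_grid[0]) | (n > self.n_grid[-1])
        if len(self.logr_grid) > 1:
            r_out = (logr < self.logr_grid[0]) | (logr > self.logr_grid[-1])
        else:
            r_out = np.zeros_like(n_out)
        if (n_out | r_out).any():
            logger.warning(
                "%d window(s) outside the null training hull; predictions "
                "clamped to the hull boundary", int((n_out | r_out).sum()))
        n = np.clip(n, self.n_grid[0], self.n_grid[-1])
        if len(self.logr_grid) == 1:
            return np.interp(n, self.n_grid, self.surface[qi, :, 0])
        logr = np.clip(logr, self.logr_grid[0], self.logr_grid[-1])
        from scipy.interpolate import RegularGridInterpolator
        interp = RegularGridInterpolator((self.n_grid, self.logr_grid),
                                         self.surface[qi])
        return interp(np.column_stack([n, logr]))

    def to_json(self) -> str:
        return json.dumps({
            "format": "starscan-expected-score-model",
            "version": 1,
            "q_grid": self.q_grid.tolist(),
            "n_grid": self.n_grid.tolist(),
            "logr_grid": self.logr_grid.tolist(),
            "surface": self.surface.tolist(),
            "meta": self.meta,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExpectedScoreModel":
        d = json.loads(text)
        if d.get("format") != "starscan-expected-score-model":
            raise ValueError("not an expected-score model file")
        return cls(d["q_grid"], d["n_grid"], d["logr_grid"], d["surface"],
                   d.get("meta"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ExpectedScoreModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _bin_edges(values: np.ndarray, max_bins: int) -> np.ndarray:
    uniq = np.unique(values)
    if len(uniq) <= max_bins:
        # one bin per observed value
        return np.concatenate([uniq - 0.5, [uniq[-1] + 0.5]])
    edges = np.unique(np.quantile(values, np.linspace(0, 1, max_bins + 1)))
    edges[0] -= 0.5
    edges[-1] += 0.5
    return edges


def _gcv_wls(formula_rhs_options, data, weights):
    """Fit WLS for each candidate RHS; return the fit minimizing GCV."""
    best = None
    for rhs in formula_rhs_options:
        try:
            res = smf.wls(f"value ~ {rhs}", data=data, weights=weights).fit()
        except Exception:  # singular design for this df, try the next
            continue
        n = len(data)
        edf = res.df_model + 1
        if n <= edf:
            continue
        gcv = (res.ssr / n) / (1 - edf / n) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, res)
    if best is None:
        raise ValueError("quantile surface fit failed for every basis size; "
                         "simulate more null data")
    return best[1]


def fit_expected_model(records: pd.DataFrame,
                       q_grid=(0.5, 0.9, 0.95, 0.99), *,
                       min_records: int = 5000, min_per_bin: int = 20,
                       max_n_bins: int = 25, max_r_bins: int = 10,
                       meta=None) -> ExpectedScoreModel:
    """Fit the expected-S* quantile surface from null score records.

    ``records`` needs columns sstar, n_snps, recomb_rate (one row per scored
    null window x individual). Empirical q-quantiles of positive S* are taken
    within (n_snps, log10 rate decile) bins and smoothed by GCV-selected
    B-spline regression, weighted by bin counts.
    """
    q_grid = tuple(sorted(float(q) for q in q_grid))
    if not all(0 < q < 1 for q in q_grid):
        raise ValueError("quantiles must lie in (0, 1)")
    df = records.loc[records["sstar"] > 0,
                     ["sstar", "n_snps", "recomb_rate"]].copy()
    if len(df) < min_records:
        raise ValueError(
            f"only {len(df)} positive-score null records; at least "
            f"{min_records} required — simulate more replicates")
    if df["n_snps"].nunique() < 5:
        raise ValueError("fewer than 5 distinct mutation counts in the null "
                         "records; simulate longer sequences")
    df["logr"] = np.log10(np.maximum(df["recomb_rate"], RATE_FLOOR))

    n_edges = _bin_edges(df["n_snps"].to_numpy(float), max_n_bins)
    r_uniq = np.unique(df["logr"])
    r_varies = len(r_uniq) > 1
    if r_varies:
        r_edges = _bin_edges(df["logr"].to_numpy(float), max_r_bins)
        df["rbin"] = np.clip(np.digitize(df["logr"], r_edges) - 1, 0,
                             len(r_edges) - 2)
    else:
        df["rbin"] = 0
    df["nbin"] = np.clip(np.digitize(df["n_snps"], n_edges) - 1, 0,
                         len(n_edges) - 2)

    cells = []
    for (nb, rb), grp in df.groupby(["nbin", "rbin"]):
        if len(grp) < min_per_bin:
            continue
        row = {"n": grp["n_snps"].mean(), "logr": grp["logr"].mean(),
               "count": len(grp)}
        for q in q_grid:
            # Weibull plotting position: E[F(X_(k))] = k/(n+1), so the
            # exceedance probability of the estimate is unbiased at 1-q.
            row[f"q{q}"] = float(np.quantile(grp["sstar"], q,
                                             method="weibull"))
        cells.append(row)
    cells = pd.DataFrame(cells)
    if len(cells) < 5:
        raise ValueError("fewer than 5 populated covariate bins; simulate "
                         "more null data or lower min_per_bin")

    n_uniq_cells = cells["n"].nunique()
    df_options = [d for d in (3, 4, 5, 6, 8) if d < n_uniq_cells]
    rhs_options = [f"bs(n, df={d}, degree=3)" if d > 3 else "n"
                   for d in df_options] or ["n"]
    if r_varies and cells["logr"].nunique() > 3:
        rhs_options = [r + " + bs(logr, df=3, degree=2)" for r in rhs_options] \
            + rhs_options

    n_grid = np.linspace(cells["n"].min(), cells["n"].max(),
                         min(120, max(20, int(cells["n"].max()
                                              - cells["n"].min()) + 1)))
    logr_grid = (np.linspace(cells["logr"].min(), cells["logr"].max(), 11)
                 if r_varies else np.array([float(r_uniq[0])]))
    grid = pd.DataFrame(
        [(n, r) for n in n_grid for r in logr_grid], columns=["n", "logr"])

    surface = np.empty((len(q_grid), len(n_grid), len(logr_grid)))
    for k, q in enumerate(q_grid):
        data = cells.rename(columns={f"q{q}": "value"})
        res = _gcv_wls(rhs_options, data, data["count"])
        pred = np.asarray(res.predict(grid), dtype=float)
        surface[k] = np.clip(pred.reshape(len(n_grid), len(logr_grid)), 0,
                             None)
    surface = np.sort(surface, axis=0)  # monotone in q pointwise

    meta = dict(meta or {})
    meta.setdefault("n_records", int(len(df)))
    meta.setdefault("n_cells", int(len(cells)))
    return ExpectedScoreModel(q_grid, n_grid, logr_grid, surface, meta)


def call_outliers(scores: pd.DataFrame, model: ExpectedScoreModel, q: float,
                  recomb=None) -> pd.DataFrame:
    """Flag windows whose observed S* strictly exceeds the expected S* at q.

    ``scores`` is an `sstar_scan` table. The recombination covariate comes
    from a ``recomb_rate`` column if present, otherwise from ``recomb``
    (a RecombMap or scalar rate). Windows with S* = 0 are never flagged.
    """
    out = scores.copy()
    if "recomb_rate" not in out.columns:
        if recomb is None:
            raise ValueError("scores lack a recomb_rate column and no "
                             "recombination map/rate was given")
        out["recomb_rate"] = [
            local_recomb_rate(Window(r.chrom, int(r.start), int(r.end)), recomb)
            for r in out.itertuples()]
    nsnps = out["n_snps_window"] if "n_snps_window" in out.columns \
        else out["n_snps"]
    out["expected_sstar"] = model.predict(nsnps.to_numpy(float),
                                          out["recomb_rate"].to_numpy(float), q)
    out["quantile"] = q
    out["is_outlier"] = (out["sstar"] > 0) & (out["sstar"]
                                              > out["expected_sstar"])
    return out
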