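"""Effective-wavelength (EW) selection: BW, SPA and GAPLS.

Full Vis/NIR spectra carry hundreds of strongly collinear bands; a handful of
effective wavelengths usually carries nearly all of the predictive
information and is what a practical multispectral sorter would implement.
Three selectors are provided:

* **BW** — rank bands by the absolute weighted regression coefficients of the
  best full-spectrum PLSR calibration model; large |BW| marks influential
  bands.  A peak-picking mode restricts the ranking to local extrema of the
  |BW| curve, so the selection spreads across distinct spectral features
  instead of crowding one peak.
* **SPA** (successive projections algorithm) — forward chains built by
  repeatedly taking the band with the largest projection onto the orthogonal
  complement of the chain so far (minimum collinearity); every start band and
  chain length is scored by the validation RMSE (RMSEV) of an MLR model, and
  the global minimizer wins.
* **GAPLS** — many short, seeded runs of a binary genetic algorithm whose
  fitness is cross-validated PLS RMSECV; per-band selection frequencies,
  weighted by each run's best CV explained variance, are aggregated and the
  most frequently chosen bands become the EWs.

All tie-breaks resolve to the lowest band index, so every selector is
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
from scipy.signal import find_peaks

from .chemometrics import RegressionModel, SpectralDataset, fit_mlr, predict, _nipals_coefs

__all__ = [
    "WavelengthSelection",
    "bw_select",
    "spa_select",
    "spa_chain",
    "gapls_select",
    "reduction_percent",
]


@dataclass
class WavelengthSelection:
    """An ordered effective-wavelength subset with per-band relevance scores.

    ``scores`` holds |BW| for BW, the (1-based, negated) projection order for
    SPA so that earlier chain members score higher, and the weighted
    selection frequency for GAPLS.
    """

    method: str
    indices: np.ndarray
    wavelengths: np.ndarray
    scores: np.ndarray
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("selected band indices must be unique")
        if not (len(self.indices) == len(self.wavelengths) == len(self.scores)):
            raise ValueError("indices, wavelengths and scores must align")
        if len(self.indices) < 1:
            raise ValueError("a selection must contain at least one band")

    @property
    def n_selected(self) -> int:
        return len(self.indices)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "method": self.method,
                    "indices": self.indices.tolist(),
                    "wavelengths": self.wavelengths.tolist(),
                    "scores": self.scores.tolist(),
                },
                indent=2,
            )
        )

    def to_csv(self, path: str | Path) -> None:
        lines = ["method,rank,band_index,wavelength_nm,score"]
        for rank, (i, wl, s) in enumerate(
            zip(self.indices, self.wavelengths, self.scores), start=1
        ):
            lines.append(f"{self.method},{rank},{i},{wl:.4f},{s:.6g}")
        Path(path).write_text("\n".join(lines) + "\n")


def reduction_percent(n_selected: int, n_total: int) -> float:
    """Percentage of bands removed by a selection (e.g. 7 of 512 -> 98.6%)."""
    if not 1 <= n_selected <= n_total:
        raise ValueError("need 1 <= n_selected <= n_total")
    return 100.0 * (1.0 - n_selected / n_total)


# ---------------------------------------------------------------------------
# BW
# ---------------------------------------------------------------------------

def bw_select(plsr: RegressionModel, k: int, peak_picking: bool = False) -> WavelengthSelection:
    """Top-k bands by |weighted regression coefficient| of a fitted PLSR.

    With ``peak_picking``, candidates are restricted to local maxima of the
    |BW| curve first (padded with the largest remaining bands if fewer than k
    peaks exist), so selections land on distinct spectral features.
    Returned in descending |BW| order.
    """
    if plsr.family != "PLSR" or plsr.coefficients is None:
        raise ValueError("bw_select needs a fitted PLSR model")
    b = np.abs(plsr.coefficients)
    if not 1 <= k <= len(b):
        raise ValueError(f"k must be in [1, {len(b)}]")
    if peak_picking:
        peaks, _ = find_peaks(b)
        order = peaks[np.argsort(-b[peaks], kind="stable")]
        if len(order) < k:
            rest = np.setdiff1d(np.arange(len(b)), order)
            order = np.concatenate([order, rest[np.argsort(-b[rest], kind="stable")]])
        idx = order[:k]
    else:
        idx = np.argsort(-b, kind="stable")[:k]
    return WavelengthSelection(
        method="BW",
        indices=idx,
        wavelengths=plsr.wavelengths[idx],
        scores=b[idx],
    )


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def spa_chain(Xn: np.ndarray, start: int, length: int) -> list[int]:
    """One SPA chain: starting at column ``start``, repeatedly append the
    column with maximal norm after projection onto the orthogonal complement
    of the chain span.  ``Xn`` should be centered/normalized columns.
    Ties break to the lowest index; columns whose residual norm vanishes
    (exact collinearity) are never selected.
    """
    p = Xn.shape[1]
    proj = Xn.astype(float).copy()
    chain = [start]
    for _ in range(length - 1):
        x = proj[:, chain[-1]]
        nx2 = x @ x
        if nx2 <= 0:
            break
        proj = proj - np.outer(x, (x @ proj) / nx2)
        norms = np.linalg.norm(proj, axis=0)
        norms[chain] = -1.0
        best = int(np.argmax(norms))  # argmax -> first (lowest) index on ties
        if norms[best] <= 1e-10:
            break
        chain.append(best)
    return chain


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray,
    max_vars: int,
    val_fraction: float = 1 / 3,
    seed: int = 0,
) -> WavelengthSelection:
    """Successive projections algorithm finalized by minimum MLR RMSEV.

    The calibration samples are split (seeded, at ``val_fraction``) into an
    internal calibration and validation part.  For every start band and every
    chain length m in [1, max_vars], the projection chain is built on the
    centered, unit-norm internal-calibration columns, an MLR model is fitted
    on the chain, and its RMSE on the validation part (RMSEV) is recorded.
    The chain with the global minimum RMSEV wins; ties prefer shorter chains,
    then the lower start index.  The returned order is the chain order
    (projection relevance).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    wavelengths = np.asarray(wavelengths, dtype=float)
    n, p = X.shape
    if max_vars < 1 or max_vars > p:
        raise ValueError("max_vars must be in [1, n_bands]")
    if n < max_vars + 2:
        raise ValueError("need n_samples >= max_vars + 2")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction)))
    val_idx, cal_idx = perm[:n_val], perm[n_val:]
    if len(cal_idx) < max_vars + 2:
        raise ValueError("internal calibration part too small for max_vars; lower max_vars")

    Xcal, ycal = X[cal_idx], y[cal_idx]
    Xval, yval = X[val_idx], y[val_idx]
    # center and scale columns to unit norm for the projection phase
    mu = Xcal.mean(axis=0)
    Xc = Xcal - mu
    norms = np.linalg.norm(Xc, axis=0)
    ok = norms > 1e-12
    if not ok.any():
        raise ValueError("all columns are constant; projections undefined")
    Xn = np.where(ok, Xc / np.where(ok, norms, 1.0), 0.0)

    best = (np.inf, None)  # (rmsev, chain)
    for start in range(p):
        if not ok[start]:
            continue
        chain = spa_chain(Xn, start, max_vars)
        for m in range(1, len(chain) + 1):
            sub = chain[:m]
            A = np.column_stack([np.ones(len(cal_idx)), Xcal[:, sub]])
            beta, *_ = np.linalg.lstsq(A, ycal, rcond=None)
            pred = beta[0] + Xval[:, sub] @ beta[1:]
            rmsev = float(np.sqrt(np.mean((yval - pred) ** 2)))
            cand = (rmsev, sub)
            if rmsev < best[0] - 1e-15:
                best = cand
            elif best[1] is not None and abs(rmsev - best[0]) <= 1e-15:
                if (len(sub), sub) < (len(best[1]), best[1]):
                    best = cand
    if best[1] is None:
        raise ValueError("SPA found no usable chain (rank-deficient data)")
    chain = np.asarray(best[1], dtype=int)
    return WavelengthSelection(
        method="SPA",
        indices=chain,
        wavelengths=wavelengths[chain],
        scores=-np.arange(1, len(chain) + 1, dtype=float),
        extras={"rmsev": best[0], "val_indices": val_idx.tolist()},
    )


# ---------------------------------------------------------------------------
# GAPLS
# ---------------------------------------------------------------------------

def _pls_cv_rmse(X: np.ndarray, y: np.ndarray, n_folds: int, max_lvs: int, rng: np.random.Generator) -> float:
    """k-fold CV RMSE of PLS on a band subset, minimized over the LV count."""
    n = len(y)
    n_folds = min(n_folds, n)
    folds = np.array_split(rng.permutation(n), n_folds)
    max_lvs = max(1, min(max_lvs, X.shape[1], n - max(len(f) for f in folds) - 1))
    preds = np.full((n, max_lvs), np.nan)
    for f in folds:
        keep = np.setdiff1d(np.arange(n), f)
        coefs, _ = _nipals_coefs(X[keep], y[keep], max_lvs)
        for a in range(max_lvs):
            b0, B = coefs[min(a, len(coefs) - 1)]
            preds[f, a] = b0 + X[f] @ B
    rmses = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return float(np.min(rmses))


def gapls_select(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray,
    runs: int = 100,
    seed: int = 0,
    population: int = 30,
    evaluations: int = 100,
    mutation_prob: float = 0.01,
    crossover_prob: float = 0.5,
    max_active: int = 30,
    n_folds: int = 5,
    max_lvs: int = 10,
    freq_cutoff: float | None = None,
    top_k: int | None = None,
) -> WavelengthSelection:
    """Genetic algorithm - PLS selection aggregated over many short runs.

    Each run evolves binary chromosomes over the bands (fitness = k-fold PLS
    RMSECV, at most ``evaluations`` fitness calls) and records its best
    chromosome.  Band frequencies over runs are weighted by the run's best CV
    explained variance, so uninformative runs count less.  The EWs are the
    bands above ``freq_cutoff``, or the ``top_k`` most frequent, or (default)
    all bands reaching at least half the maximum weighted frequency; returned
    in descending frequency order, ties to the lower index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    wavelengths = np.asarray(wavelengths, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("GAPLS needs at least 10 samples")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    var_y = float(np.var(y))
    if var_y == 0:
        raise ValueError("y has zero variance")

    freq = np.zeros(p)
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.spawn(runs)
    p_init = min(0.5, 5.0 / p)

    for run_seed in run_seeds:
        rng = np.random.default_rng(run_seed)

        def repair(c: np.ndarray) -> np.ndarray:
            act = np.flatnonzero(c)
            if len(act) == 0:
                c[rng.integers(p)] = True
            elif len(act) > max_active:
                off = rng.choice(act, size=len(act) - max_active, replace=False)
                c[off] = False
            return c

        def fitness(c: np.ndarray) -> float:
            sub = np.flatnonzero(c)
            return _pls_cv_rmse(X[:, sub], y, n_folds, max_lvs, rng)

        pop = [repair(rng.random(p) < p_init) for _ in range(population)]
        fits = [fitness(c) for c in pop]
        budget = max(0, evaluations - population)
        best_i = int(np.argmin(fits))
        best_c, best_f = pop[best_i].copy(), fits[best_i]
        while budget > 0:
            # tournament parents
            parents = []
            for _ in range(2):
                a, bdx = rng.integers(population, size=2)
                parents.append(pop[a] if fits[a] <= fits[bdx] else pop[bdx])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < crossover_prob:
                cut = rng.integers(1, p)
                c1 = np.concatenate([parents[0][:cut], parents[1][cut:]])
                c2 = np.concatenate([parents[1][:cut], parents[0][cut:]])
            for c in (c1, c2):
                flip = rng.random(p) < mutation_prob
                c ^= flip
                repair(c)
                f = fitness(c)
                budget -= 1
                # replace current worst if better
                worst = int(np.argmax(fits))
                if f < fits[worst]:
                    pop[worst], fits[worst] = c, f
                if f < best_f:
                    best_c, best_f = c.copy(), f
                if budget <= 0:
                    break
        weight = max(0.0, 1.0 - best_f**2 / var_y)
        freq[np.flatnonzero(best_c)] += weight

    if freq.max() <= 0:
        raise ValueError("no GAPLS run produced a feasible chromosome")
    if top_k is not None:
        order = np.argsort(-freq, kind="stable")
        sel = order[: int(top_k)]
    else:
        cutoff = freq_cutoff if freq_cutoff is not None else 0.5 * freq.max()
        sel = np.flatnonzero(freq >= cutoff)
        sel = sel[np.argsort(-freq[sel], kind="stable")]
    if len(sel) == 0:
        raise ValueError("frequency cutoff removed every band")
    return WavelengthSelection(
        method="GAPLS",
        indices=sel,
        wavelengths=wavelengths[sel],
        scores=freq[sel],
        extras={"frequencies": freq.tolist(), "runs": runs},
    )
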