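"""Monte-Carlo cross-validated PLS ensembles and biplot projections.

A single PLS fit depends on which samples it saw; the pipeline
therefore reports ensemble averages over repeated random train/holdout
splits (by default 1,000 runs with 10% holdout). Because PLS components
carry an arbitrary sign, each run's components are sign-aligned to a
reference run before averaging — naive averaging can cancel a
component entirely. Biplots project the averaged predictor and response
loadings onto the first two latent variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pls import PLS, PLSResults, press

__all__ = [
    "MccvEnsemble",
    "AveragedModel",
    "BiplotData",
    "run_mccv",
    "align_and_average",
    "biplot_data",
]


@dataclass
class MccvEnsemble:
    """Results of repeated random-split PLS fits.

    ``runs`` holds the per-run :class:`~cardiopls.pls.PLSResults`;
    ``holdout_press`` the per-run PRESS on the held-out samples;
    ``holdout_indices`` the sample indices held out per run.
    """

    runs: list[PLSResults]
    holdout_press: np.ndarray
    holdout_indices: list[np.ndarray]
    holdout_fraction: float
    seed: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def average(self) -> "AveragedModel":
        return align_and_average(self)


@dataclass
class AveragedModel:
    """Sign-aligned, entrywise-averaged arrays of an MCCV ensemble."""

    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    beta: np.ndarray
    var_explained_x: np.ndarray
    var_explained_y: np.ndarray
    x_names: list[str]
    y_names: list[str]
    n_runs: int
    # standard errors of the mean, per entry
    x_loadings_se: np.ndarray | None = None
    y_loadings_se: np.ndarray | None = None
    beta_se: np.ndarray | None = None


@dataclass
class BiplotData:
    """Variable projections onto the first two latent variables."""

    input_points: dict[str, np.ndarray]
    output_points: dict[str, np.ndarray]
    axis_variance: tuple[float, float]


def run_mccv(X, Y, n_components: int = 4, n_runs: int = 1000,
             holdout: float = 0.1, seed: int = 0, scale: bool = True,
             algorithm: str = "nipals") -> MccvEnsemble:
    """Fit PLS on repeated random train/holdout splits.

    Each run draws ``round(holdout * n)`` samples without replacement
    as a test set (at least 1 when ``holdout > 0``), fits on the rest
    and records the holdout PRESS. Run ``i`` uses the reproducible
    stream ``default_rng([seed, i])``, so any run can be regenerated in
    isolation.
    """
    import pandas as pd

    x_names = [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) \
        else None
    y_names = [str(c) for c in Y.columns] if isinstance(Y, pd.DataFrame) \
        else None
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    n_hold = int(round(holdout * n))
    if holdout > 0:
        n_hold = max(n_hold, 1)
    if n - n_hold <= n_components + 1:
        raise ValueError(
            f"holdout of {n_hold} leaves {n - n_hold} training samples; "
            f"need more than {n_components + 1}"
        )
    runs, press_vals, hold_idx = [], [], []
    for i in range(n_runs):
        rng = np.random.default_rng([seed, i])
        test = np.sort(rng.choice(n, size=n_hold, replace=False)) \
            if n_hold else np.array([], dtype=int)
        train = np.setdiff1d(np.arange(n), test)
        Ytr = pd.DataFrame(Y[train], columns=y_names) if y_names \
            else Y[train]
        Xtr = pd.DataFrame(X[train], columns=x_names) if x_names \
            else X[train]
        res = PLS(Ytr, Xtr, n_components=n_components,
                  scale=scale, algorithm=algorithm).fit()
        runs.append(res)
        hold_idx.append(test)
        press_vals.append(
            press(Y[test], res.predict(X[test])) if n_hold else 0.0
        )
    return MccvEnsemble(runs, np.asarray(press_vals), hold_idx,
                        holdout, seed)


def _align_signs(ref: PLSResults, res: PLSResults) -> np.ndarray:
    """Per-component sign flips making res agree with ref.

    Agreement is judged by the inner product of the concatenated X and
    Y loading vectors; beta is invariant to these flips, scores and
    loadings are not.
    """
    k = ref.x_loadings.shape[1]
    signs = np.ones(k)
    for a in range(k):
        dot = ref.x_loadings[:, a] @ res.x_loadings[:, a] \
            + ref.y_loadings[:, a] @ res.y_loadings[:, a]
        if dot < 0:
            signs[a] = -1.0
    return signs


def align_and_average(ens: MccvEnsemble) -> AveragedModel:
    """Average ensemble arrays after sign-aligning to the first run."""
    ref = ens.runs[0]
    shapes = {(r.x_weights.shape, r.y_loadings.shape) for r in ens.runs}
    if len(shapes) != 1:
        raise ValueError("inconsistent array shapes across runs")
    Ws, Ps, Qs, Bs, vx, vy = [], [], [], [], [], []
    for res in ens.runs:
        s = _align_signs(ref, res)
        Ws.append(res.x_weights * s)
        Ps.append(res.x_loadings * s)
        Qs.append(res.y_loadings * s)
        Bs.append(res.beta)
        vx.append(res.var_explained_x)
        vy.append(res.var_explained_y)
    Ws, Ps, Qs, Bs = map(np.stack, (Ws, Ps, Qs, Bs))
    nrun = len(ens.runs)
    sem = (lambda a: a.std(axis=0, ddof=1) / np.sqrt(nrun)) if nrun > 1 \
        else (lambda a: np.zeros(a.shape[1:]))
    return AveragedModel(
        x_weights=Ws.mean(axis=0), x_loadings=Ps.mean(axis=0),
        y_loadings=Qs.mean(axis=0), beta=Bs.mean(axis=0),
        var_explained_x=np.stack(vx).mean(axis=0),
        var_explained_y=np.stack(vy).mean(axis=0),
        x_names=ref.model.x_names, y_names=ref.model.y_names,
        n_runs=nrun,
        x_loadings_se=sem(Ps), y_loadings_se=sem(Qs), beta_se=sem(Bs),
    )


def biplot_data(avg: AveragedModel) -> BiplotData:
    """Project averaged loadings onto latent variables 1 and 2."""
    if avg.x_loadings.shape[1] < 2:
        raise ValueError("biplot requires at least 2 components")
    inputs = {name: avg.x_loadings[j, :2].copy()
              for j, name in enumerate(avg.x_names)}
    outputs = {name: avg.y_loadings[j, :2].copy()
               for j, name in enumerate(avg.y_names)}
    axis_var = (float(avg.var_explained_y[0]), float(avg.var_explained_y[1]))
    return BiplotData(inputs, outputs, axis_var)
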