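"""Cross-stratum transferability audit of PLS models.

Does a model trained on one sex predict the other? Three Monte-Carlo
designs answer this for the modifier -> ion-channel model:

* ``original`` — per run, draw ``n_train`` samples (default 84, the
  size of the smaller stratum) from the training stratum, hold out 10%
  for a within-stratum test, fit, then predict the *entire* other
  stratum.
* ``reduced`` — as original, but the training stratum is first
  down-sampled by histogram matching on a confounder (total ischemic
  time by default) so its confounder distribution matches the other
  stratum.
* ``mixed`` — per run, equal numbers from both strata are pooled,
  split into equal-composition train and test halves; a null design:
  the model has seen both strata, so errors should centre on zero.

Signed prediction errors (prediction - actual, so underestimation is
negative) are pooled per output gene and tested stratum over all runs.
Ashman's D, sqrt(2)|mu1 - mu2| / sqrt(s1^2 + s2^2), quantifies how
separable the two strata's error distributions are; D > 2 marks clearly
separable distributions (D > 1 a weaker signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import PLS

__all__ = [
    "TransferDesign",
    "TransferResult",
    "histogram_match",
    "run_transfer",
    "ashman_d",
    "ashman_d_params",
    "separability_report",
    "confounder_score_correlation",
]


def ashman_d_params(mu1: float, mu2: float, sigma1: float,
                    sigma2: float) -> float:
    """Ashman's D from distribution parameters:
    ``sqrt(2) * |mu1 - mu2| / sqrt(sigma1^2 + sigma2^2)``."""
    denom = np.sqrt(sigma1 ** 2 + sigma2 ** 2)
    if denom == 0:
        raise ValueError("zero combined variance")
    return float(np.sqrt(2.0) * abs(mu1 - mu2) / denom)


def ashman_d(errors_a, errors_b) -> float:
    """Sample Ashman's D between two error populations.

    Uses sample means and n-1 variances.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each error vector needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb == 0:
        raise ValueError("zero combined variance")
    return ashman_d_params(a.mean(), b.mean(), np.sqrt(va), np.sqrt(vb))


def histogram_match(meta_large: pd.DataFrame, meta_small: pd.DataFrame,
                    column: str = "ischemic_time",
                    bin_width: float | None = None,
                    rng: np.random.Generator | None = None) -> list[str]:
    """Down-sample the larger stratum to match a confounder histogram.

    Bins both strata's ``column`` values on a common grid; within each
    bin, samples are removed uniformly at random from the large stratum
    until its count equals the small stratum's (bins where the large
    stratum already has fewer keep everything, with a warning). Returns
    the retained large-stratum sample ids.

    ``bin_width`` defaults to the Freedman–Diaconis width computed on
    the small stratum.
    """
    rng = rng if rng is not None else np.random.default_rng()
    for name, df in (("large", meta_large), ("small", meta_small)):
        if column not in df.columns:
            raise KeyError(f"{name} stratum metadata lacks column {column!r}")
        if df[column].isna().any():
            raise ValueError(f"{name} stratum has missing {column!r} values")
    big = meta_large[column].to_numpy(dtype=float)
    small = meta_small[column].to_numpy(dtype=float)
    lo = min(big.min(), small.min())
    hi = max(big.max(), small.max())
    if big.max() < small.min() or small.max() < big.min():
        raise ValueError(f"{column!r} ranges of the two strata do not overlap")
    if bin_width is None:
        iqr = np.subtract(*np.percentile(small, [75, 25]))
        bin_width = 2.0 * iqr / len(small) ** (1 / 3)
        if bin_width <= 0:
            bin_width = (hi - lo) / 10 or 1.0
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges[-1] <= hi:
        edges = np.append(edges, edges[-1] + bin_width)
    ids = meta_large.index.to_numpy()
    big_bin = np.digitize(big, edges) - 1
    small_bin = np.digitize(small, edges) - 1
    kept: list[str] = []
    for b in range(len(edges) - 1):
        in_bin = ids[big_bin == b]
        target = int((small_bin == b).sum())
        if len(in_bin) <= target:
            if len(in_bin) < target and len(in_bin) > 0:
                warnings.warn(
                    f"bin {b}: large stratum has {len(in_bin)} < {target} "
                    "samples; keeping all", stacklevel=2,
                )
            kept.extend(in_bin)
        else:
            kept.extend(rng.choice(in_bin, size=target, replace=False))
    order = {s: i for i, s in enumerate(meta_large.index)}
    return sorted(kept, key=order.get)


@dataclass
class TransferDesign:
    """Configuration of one transfer-audit experiment."""

    design: str = "original"          # original | reduced | mixed
    train_stratum: str = "male"
    n_train: int = 84
    holdout: float = 0.1
    n_runs: int = 1000
    n_components: int = 4
    confounder: str = "ischemic_time"
    bin_width: float | None = None    # None -> Freedman-Diaconis
    scale: bool = True

    def __post_init__(self) -> None:
        if self.design not in ("original", "reduced", "mixed"):
            raise ValueError(f"unknown design {self.design!r}")
        if not 0 < self.holdout < 1:
            raise ValueError("holdout must be in (0, 1)")
        if self.n_runs < 1 or self.n_train < 2:
            raise ValueError("n_runs >= 1 and n_train >= 2 required")


@dataclass
class TransferResult:
    """Pooled signed prediction errors and per-gene Ashman's D.

    ``errors[stratum]`` is an (n_runs * per-run test size) x genes
    array of prediction - actual values; ``run_means[stratum]`` the
    per-run mean error (n_runs x genes), used for standard errors.
    """

    design: TransferDesign
    gene_names: list[str]
    errors: dict[str, np.ndarray]
    run_means: dict[str, np.ndarray]
    sample_mean_errors: dict[str, pd.DataFrame]
    seed: int
    ashman: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        strata = list(self.errors)
        if len(strata) != 2:
            raise ValueError("expected errors for exactly two strata")
        a, b = (self.errors[s] for s in strata)
        d = [ashman_d(a[:, j], b[:, j]) for j in range(len(self.gene_names))]
        self.ashman = pd.Series(d, index=self.gene_names, name="ashman_d")

    def error_summary(self) -> pd.DataFrame:
        """Mean, SD and SE of the pooled errors per gene and stratum.

        Errors from different runs reuse the same cohort samples and
        are strongly dependent, so ``se_mean`` treats samples — not
        runs — as the independent unit: it is the SD over per-sample
        mean errors divided by sqrt(number of distinct tested samples).
        """
        rows = []
        for stratum, err in self.errors.items():
            sm = self.sample_mean_errors[stratum]
            n_samp = sm.shape[0]
            se = sm.std(axis=0, ddof=1).to_numpy() / np.sqrt(n_samp) \
                if n_samp > 1 else np.zeros(sm.shape[1])
            for j, g in enumerate(self.gene_names):
                rows.append({
                    "gene": g, "stratum": stratum,
                    "mean_error": err[:, j].mean(),
                    "sd_error": err[:, j].std(ddof=1),
                    "se_mean": se[j],
                    "n_errors": err.shape[0],
                    "n_samples": n_samp,
                })
        return pd.DataFrame(rows)


def _stratum_ids(meta: pd.DataFrame, stratum: str) -> np.ndarray:
    ids = meta.index[meta["sex"] == stratum].to_numpy()
    if ids.size == 0:
        raise ValueError(f"no samples in stratum {stratum!r}")
    return ids


def run_transfer(X: pd.DataFrame, Y: pd.DataFrame, meta: pd.DataFrame,
                 design: TransferDesign, seed: int = 0) -> TransferResult:
    """Run a Monte-Carlo transfer audit.

    X and Y are samples x genes frames (CLR units) over the same
    samples; ``meta`` must carry a ``sex`` column (and the confounder
    column for the reduced design). Run ``i`` draws from the stream
    ``default_rng([seed, i])`` so results are reproducible run by run.
    """
    if not (X.index.equals(Y.index)):
        raise ValueError("X and Y must be over identical samples")
    meta = meta.loc[X.index]
    strata = ["female", "male"]
    train_s = design.train_stratum
    if train_s not in strata:
        raise ValueError(f"train_stratum must be one of {strata}")
    other_s = "male" if train_s == "female" else "female"
    train_ids_all = _stratum_ids(meta, train_s)
    other_ids = _stratum_ids(meta, other_s)

    if design.design in ("original", "reduced") \
            and design.n_train > len(train_ids_all):
        raise ValueError(
            f"n_train={design.n_train} exceeds the {len(train_ids_all)} "
            f"available {train_s} samples"
        )
    n_hold = max(1, int(round(design.holdout * design.n_train)))
    if design.n_train - n_hold <= design.n_components + 1:
        raise ValueError(
            "holdout leaves too few training samples for "
            f"{design.n_components} components"
        )

    Xv, Yv = X.to_numpy(), Y.to_numpy()
    pos = {s: i for i, s in enumerate(X.index)}
    n_genes = Y.shape[1]
    errors = {s: [] for s in strata}
    run_means = {s: [] for s in strata}
    samp_sum = {s: np.zeros((len(X.index), n_genes)) for s in strata}
    samp_count = {s: np.zeros(len(X.index)) for s in strata}

    for i in range(design.n_runs):
        rng = np.random.default_rng([seed, i])
        if design.design == "mixed":
            n_half = min(len(train_ids_all), len(other_ids),
                         design.n_train) // 2 * 2
            picks = {
                s: rng.permutation(_stratum_ids(meta, s))[:n_half]
                for s in strata
            }
            train_ids = np.concatenate(
                [picks[s][: n_half // 2] for s in strata])
            test_by_stratum = {
                s: picks[s][n_half // 2: n_half] for s in strata}
        else:
            pool = train_ids_all
            if design.design == "reduced":
                with warnings.catch_warnings():
                    if i > 0:  # surface under-filled-bin warnings once
                        warnings.simplefilter("ignore", UserWarning)
                    kept = histogram_match(
                        meta.loc[train_ids_all], meta.loc[other_ids],
                        column=design.confounder,
                        bin_width=design.bin_width, rng=rng,
                    )
                pool = np.asarray(kept)
            n_take = min(design.n_train, len(pool))
            chosen = rng.choice(pool, size=n_take, replace=False)
            hold = chosen[:n_hold]
            train_ids = chosen[n_hold:]
            test_by_stratum = {train_s: hold, other_s: other_ids}
        tr = [pos[s] for s in train_ids]
        res = PLS(Yv[tr], Xv[tr], n_components=design.n_components,
                  scale=design.scale, algorithm="nipals").fit()
        for s, ids in test_by_stratum.items():
            te = [pos[x] for x in ids]
            err = res.predict(Xv[te]) - Yv[te]  # prediction - actual
            errors[s].append(err)
            run_means[s].append(err.mean(axis=0))
            samp_sum[s][te] += err
            samp_count[s][te] += 1
    sample_means = {}
    for s in strata:
        tested = samp_count[s] > 0
        sample_means[s] = pd.DataFrame(
            samp_sum[s][tested] / samp_count[s][tested, None],
            index=X.index[tested], columns=Y.columns,
        )
    return TransferResult(
        design=design, gene_names=[str(c) for c in Y.columns],
        errors={s: np.vstack(errors[s]) for s in strata},
        run_means={s: np.vstack(run_means[s]) for s in strata},
        sample_mean_errors=sample_means,
        seed=seed,
    )


def separability_report(result: TransferResult,
                        threshold: float = 2.0) -> pd.DataFrame:
    """Per-gene Ashman's D table with a separability flag at ``threshold``."""
    d = result.ashman
    return pd.DataFrame({
        "gene": d.index,
        "ashman_d": d.to_numpy(),
        "separable": d.to_numpy() > threshold,
        "threshold": threshold,
    }).reset_index(drop=True)


def confounder_score_correlation(scores: np.ndarray, meta: pd.DataFrame,
                                 fields: list[str] | None = None
                                 ) -> pd.DataFrame:
    """Pearson correlation of PLS sample scores with metadata covariates.

    A tabular stand-in for embedding-based confounder visualisation:
    rows are latent variables, columns metadata fields (age, BMI, RIN,
    ischemic time by default), entries the correlation of the score
    with the covariate over samples with non-missing values.
    """
    fields = fields or ["age", "bmi", "rin", "ischemic_time"]
    fields = [f for f in fields if f in meta.columns]
    scores = np.asarray(scores, dtype=float)
    out = {}
    for f in fields:
        v = meta[f].to_numpy(dtype=float)
        ok = np.isfinite(v)
        col = []
        for a in range(scores.shape[1]):
            s = scores[ok, a]
            col.append(np.corrcoef(s, v[ok])[0, 1]
                       if s.std() > 0 and v[ok].std() > 0 else np.nan)
        out[f] = col
    return pd.DataFrame(
        out, index=[f"LV{a + 1}" for a in range(scores.shape[1])])
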