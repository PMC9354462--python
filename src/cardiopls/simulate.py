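"""Synthetic sex-stratified compositional expression cohorts.

The generator emulates the statistical structure of the left-ventricle
bulk RNA-seq data the pipeline targets, without attempting to match any
real gene's expression level:

* positive compositional TPM rows summing to 1e6;
* a shared latent-factor cascade modifier -> TF -> ion channel: the
  modifier block loads directly on a few latent factors, the TF block
  is a linear map of the modifier signal, the IC block a linear map of
  the TF signal, all with log10-scale residual noise;
* a designated ion channel (the Na/K-pump analogue) driven by an
  independent factor, i.e. regulated orthogonally to the rest;
* sex-specific regulation: for selected IC genes the female coupling
  onto a repressive drive (baseline -1 plus a small factor loading)
  differs by ``sex_delta`` — a negative delta weakens the repression,
  raising female expression so a male-trained model underestimates it;
* a continuous confounder (total ischemic time, minutes) acting
  additively on the log scale, with males drawn from a longer-tailed
  distribution than females;
* a reference (GAPDH-like) gene whose TPM spread mimics sample
  dilution, with a small rate of out-of-range values; and
* a small rate of gross outlier samples planted at an extreme position
  along the first latent factor.

Ground truth (factors, coefficient matrices, planted labels) is
returned alongside the cohort so every downstream module can be tested
against known structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix
from .panels import GenePanel

__all__ = ["SyntheticSpec", "GroundTruth", "generate_cohort",
           "truth_recovery_score"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    Defaults mirror the study conditions of the targeted dataset:
    84 female and 158 male samples, four latent factors with a dominant
    first pair, ischemic-time distributions that differ by sex, and a
    sex-specific coupling delta on the Na/Ca-exchanger analogue.
    """

    n_female: int = 84
    n_male: int = 158
    latent_rank: int = 4
    factor_scales: tuple[float, ...] | None = None  # default rank-2 dominant
    loading_scale_modifier: float = 0.35
    loading_scale_tf: float = 0.8
    sex_delta: dict[str, float] = field(
        default_factory=lambda: {"SLC8A1": -0.5})
    ic_spread: float = 0.25             # per-gene deviation from the shared axis
    orthogonal_gene: str | None = "ATP1A1"
    orthogonal_strength: float = 1.0
    confounder_effect: dict[str, float] = field(
        default_factory=lambda: {"KCNJ2": 5e-4, "GJA1": 5e-4})
    confounder_ref: float = 300.0       # minutes; effects centred here
    female_ischemic_mean: float = 300.0
    female_ischemic_sd: float = 120.0
    male_tail_scale: float = 250.0      # exponential tail added for males
    noise_sd: float = 0.1               # log10-scale residual SD (TF/IC)
    modifier_noise_sd: float | None = None  # default: same as noise_sd
    reference_mean: float = 1300.0      # TPM
    reference_sd: float = 300.0
    reference_out_rate: float = 0.03    # planted out-of-range reference values
    outlier_rate: float = 0.008         # gross score-outlier samples
    outlier_magnitude: float = 10.0     # SD units along factor 1
    n_filler: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_female + self.n_male
        if n < self.latent_rank + 5:
            raise ValueError("cohort too small for the latent rank")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.factor_scales is None:
            base = (1.0, 0.7, 0.35, 0.25, 0.2, 0.15)
            if self.latent_rank > len(base):
                raise ValueError("latent_rank too large for default scales")
            self.factor_scales = base[: self.latent_rank]
        if len(self.factor_scales) != self.latent_rank:
            raise ValueError("factor_scales length must equal latent_rank")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    factors: np.ndarray                  # samples x latent_rank
    loadings_modifier: np.ndarray        # latent_rank x n_modifiers
    map_modifier_to_tf: np.ndarray       # n_modifiers x n_tfs
    map_tf_to_ic: np.ndarray             # n_tfs x n_ics
    ic_factor_exposures: np.ndarray      # latent_rank x n_ics
    baselines: dict[str, np.ndarray]
    outlier_ids: list[str]
    reference_out_ids: list[str]
    sex_delta: dict[str, float]
    confounder_effect: dict[str, float]
    orthogonal_gene: str | None
    gene_blocks: dict[str, list[str]]

    @property
    def modifier_to_ic(self) -> np.ndarray:
        """Implied log-space linear map modifiers -> ICs."""
        return self.map_modifier_to_tf @ self.map_tf_to_ic


def _ischemic_times(spec: SyntheticSpec, sex: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    n = len(sex)
    base = rng.normal(spec.female_ischemic_mean, spec.female_ischemic_sd,
                      size=n)
    base = np.clip(base, 10.0, None)
    tail = rng.exponential(spec.male_tail_scale, size=n)
    return np.where(sex == "male", base + tail, base)


def generate_cohort(
    spec: SyntheticSpec, panel: GenePanel | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Draw one cohort from the spec.

    Returns the TPM matrix (panel genes + reference gene + filler
    genes; rows sum to 1e6), the sample-attribute table and the
    :class:`GroundTruth` record. Fully determined by ``spec.seed``.
    """
    panel = panel or GenePanel()
    rng = np.random.default_rng(spec.seed)
    nf, nm = spec.n_female, spec.n_male
    n = nf + nm
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    sex = np.array(["female"] * nf + ["male"] * nm)
    perm = rng.permutation(n)           # interleave sexes in sample order
    sex = sex[perm]

    mods = list(panel.modifier_genes)
    tfs = list(panel.tf_genes)
    ics = list(panel.ic_genes)
    r = spec.latent_rank
    scales = np.asarray(spec.factor_scales)

    z = rng.normal(size=(n, r)) * scales
    # gross outliers: extreme coordinate along factor 1
    n_out = int(round(spec.outlier_rate * n))
    out_idx = rng.choice(n, size=n_out, replace=False) if n_out else \
        np.array([], dtype=int)
    z[out_idx, 0] = spec.outlier_magnitude * scales[0]

    L = rng.normal(scale=spec.loading_scale_modifier, size=(r, len(mods)))
    A = rng.normal(scale=spec.loading_scale_tf / np.sqrt(len(mods)),
                   size=(len(mods), len(tfs)))

    base_mod = rng.uniform(0.8, 2.2, size=len(mods))
    base_tf = rng.uniform(0.8, 2.2, size=len(tfs))
    base_ic = rng.uniform(0.8, 2.2, size=len(ics))

    factor_signal = z @ L
    mod_noise = spec.modifier_noise_sd if spec.modifier_noise_sd is not None \
        else spec.noise_sd
    mod_signal = factor_signal \
        + rng.normal(scale=mod_noise, size=(n, len(mods)))
    # the cascade transmits the factor signal, not the modifier genes'
    # measurement noise: the modifier -> IC relation has latent rank r
    tf_signal = factor_signal @ A \
        + rng.normal(scale=spec.noise_sd, size=(n, len(tfs)))

    # IC factor exposures: a dominant shared co-regulation axis (factor 1)
    # with per-gene strengths and a small spread over the remaining
    # factors; the orthogonal gene is driven by factor 2 alone, i.e.
    # regulated by the modifiers in a direction orthogonal to the rest.
    E = np.zeros((r, len(ics)))
    E[0, :] = rng.uniform(0.5, 1.0, size=len(ics))
    if r > 1:
        E[1:, :] += rng.normal(scale=spec.ic_spread,
                               size=(r - 1, len(ics)))
    orth_j = ics.index(spec.orthogonal_gene) \
        if spec.orthogonal_gene in ics else None
    if orth_j is not None:
        if r < 2:
            raise ValueError("orthogonal_gene requires latent_rank >= 2")
        E[:, orth_j] = 0.0
        E[1, orth_j] = spec.orthogonal_strength
    # the TF -> IC map realising these exposures through the cascade
    B = np.linalg.pinv(L @ A) @ E
    ic_signal = (factor_signal @ A) @ B \
        + rng.normal(scale=spec.noise_sd, size=(n, len(ics)))

    # sex-specific coupling: repressive drive with baseline -1
    female = sex == "female"
    w_sex = np.zeros(r)
    w_sex[0] = 0.3
    drive = -1.0 + z @ w_sex
    for gene, delta in spec.sex_delta.items():
        if gene not in ics:
            raise ValueError(f"sex_delta gene {gene!r} not in the IC block")
        j = ics.index(gene)
        ic_signal[female, j] += delta * drive[female]

    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "sex": sex,
        "age": rng.integers(21, 71, size=n),
        "bmi": np.round(rng.normal(27.0, 4.0, size=n), 1),
        "rin": np.round(np.clip(rng.normal(7.5, 0.7, size=n), 5.0, 10.0), 1),
    })
    meta["ischemic_time"] = np.round(_ischemic_times(spec, sex, rng), 1)
    for gene, slope in spec.confounder_effect.items():
        if gene not in ics:
            raise ValueError(
                f"confounder_effect gene {gene!r} not in the IC block")
        j = ics.index(gene)
        ic_signal[:, j] += slope * (
            meta["ischemic_time"].to_numpy() - spec.confounder_ref)

    base_fill = rng.uniform(0.5, 2.5, size=spec.n_filler)
    fill_log = base_fill + rng.normal(scale=0.3, size=(n, spec.n_filler))

    log_table = np.column_stack([
        base_mod + mod_signal,
        base_tf + tf_signal,
        base_ic + ic_signal,
        fill_log,
    ])

    # reference gene: in-range by construction except planted outliers
    ref = np.clip(rng.normal(spec.reference_mean, spec.reference_sd, size=n),
                  600.0, 2400.0)
    n_refout = int(round(spec.reference_out_rate * n))
    pool = np.setdiff1d(np.arange(n), out_idx)
    ref_out_idx = rng.choice(pool, size=n_refout, replace=False) \
        if n_refout else np.array([], dtype=int)
    for i in ref_out_idx:
        ref[i] = rng.uniform(100.0, 400.0) if rng.random() < 0.5 \
            else rng.uniform(2600.0, 3500.0)

    other = 10.0 ** log_table
    row_factor = (1e6 - ref) / other.sum(axis=1)
    tpm = other * row_factor[:, None]

    genes = (mods + tfs + ics
             + [f"FILLER{j + 1:03d}" for j in range(spec.n_filler)])
    df = pd.DataFrame(tpm, index=sample_ids, columns=genes)
    df[panel.reference_gene] = ref
    expr = ExpressionMatrix(df)

    truth = GroundTruth(
        factors=z, loadings_modifier=L, map_modifier_to_tf=A,
        map_tf_to_ic=B, ic_factor_exposures=E,
        baselines={"modifier": base_mod, "TF": base_tf, "IC": base_ic},
        outlier_ids=[sample_ids[i] for i in sorted(out_idx)],
        reference_out_ids=[sample_ids[i] for i in sorted(ref_out_idx)],
        sex_delta=dict(spec.sex_delta),
        confounder_effect=dict(spec.confounder_effect),
        orthogonal_gene=spec.orthogonal_gene,
        gene_blocks={"modifier": mods, "TF": tfs, "IC": ics},
    )
    return expr, meta.set_index("sample_id", drop=False), truth


def truth_recovery_score(fitted: np.ndarray | list[np.ndarray],
                         truth: np.ndarray) -> pd.DataFrame:
    """Bias and RMSE of fitted coefficient matrices against ground truth.

    ``fitted`` may be a single matrix or a list over replicate
    cohorts. Returns a long-format table with one row per coefficient.
    """
    mats = [np.asarray(m, dtype=float) for m in
            (fitted if isinstance(fitted, list) else [fitted])]
    truth = np.asarray(truth, dtype=float)
    for m in mats:
        if m.shape != truth.shape:
            raise ValueError(
                f"fitted shape {m.shape} != truth shape {truth.shape}")
    stack = np.stack(mats)
    bias = stack.mean(axis=0) - truth
    rmse = np.sqrt(((stack - truth) ** 2).mean(axis=0))
    rows, cols = truth.shape
    idx = pd.MultiIndex.from_product(
        [range(rows), range(cols)], names=["predictor", "response"])
    return pd.DataFrame({
        "truth": truth.ravel(),
        "bias": bias.ravel(),
        "rmse": rmse.ravel(),
    }, index=idx)
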