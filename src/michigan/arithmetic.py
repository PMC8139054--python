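"""Latent-space vector arithmetic and the latent-entropy (delta-H) diagnostic.

To predict an unseen (cell type C', treatment D') combination, the mean
latent offset between cell types C' and a control cell type C_k is averaged
over the treatments Omega observed for both, and added to the codes of the
observed (C_k, D') cells:

    Zhat(C', D') = Z(C_k, D') + mean_{s in Omega} [ mean Z(C', D_s)
                                                    - mean Z(C_k, D_s) ].

The prediction is exact when cell-type offsets are homogeneous across
treatments (no interaction); the latent-entropy difference

    delta_H = H{tau_fake(Z), g(X)} - H{tau_real(Z), g(X)},
    H{tau(Z), g(X)} = -E_{tau(Z)} [ log E_{g(X)} q_phi(Z | X) ]

ranks combinations by how well the arithmetic matches the encoder: low
delta_H marks predictable (near-additive) combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GaussianPosterior

__all__ = [
    "CombinationGrid",
    "EntropyReport",
    "predict_latents",
    "predict_expression",
    "latent_entropy",
    "rank_combinations_by_delta_h",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class CombinationGrid:
    """Observed/held-out structure over (cell type, treatment) pairs."""

    cell_types: np.ndarray
    treatments: np.ndarray
    held_out: list = field(default_factory=list)  # list of (C, D) tuples

    def __post_init__(self):
        self.cell_types = np.asarray(self.cell_types)
        self.treatments = np.asarray(self.treatments)
        if self.cell_types.shape != self.treatments.shape:
            raise ValueError("cell_types and treatments lengths differ")
        held = {tuple(h) for h in self.held_out}
        observed = set(zip(self.cell_types.tolist(),
                           self.treatments.tolist())) - held
        for c, dd in held:
            if not any(cc == c for cc, _ in observed):
                raise ValueError(
                    f"held-out cell type {c!r} is never observed")
            if not any(t == dd for _, t in observed):
                raise ValueError(
                    f"held-out treatment {dd!r} is never observed")
        self.observed = observed

    def mask_observed(self) -> np.ndarray:
        held = {tuple(h) for h in self.held_out}
        return np.array([(c, t) not in held for c, t in
                         zip(self.cell_types.tolist(),
                             self.treatments.tolist())])


def predict_latents(codes: np.ndarray, cell_types, treatments,
                    target: tuple, control) -> np.ndarray:
    """Predict codes for the unseen (C', D') combination.

    Parameters
    ----------
    codes
        n x d latent codes of *observed* cells (posterior means or samples;
        record which mode upstream).
    cell_types, treatments
        Length-n label arrays aligned with ``codes``.
    target
        (C', D') pair to predict.
    control
        Control cell type C_k; (C_k, D') must be observed.

    Returns one predicted code per (C_k, D') control cell: the control code
    plus the mean latent difference Delta_{C', C_k}, averaged uniformly over
    the shared treatments Omega.
    """
    codes = np.asarray(codes, float)
    cell_types = np.asarray(cell_types)
    treatments = np.asarray(treatments)
    c_target, d_target = target

    base_mask = (cell_types == control) & (treatments == d_target)
    if not base_mask.any():
        raise ValueError(
            f"control combination ({control!r}, {d_target!r}) not observed")
    if c_target == control:
        return codes[base_mask].copy()

    shared = []
    for s in np.unique(treatments):
        if s == d_target:
            continue
        has_t = ((cell_types == c_target) & (treatments == s)).any()
        has_c = ((cell_types == control) & (treatments == s)).any()
        if has_t and has_c:
            shared.append(s)
    if not shared:
        missing = [s for s in np.unique(treatments) if s != d_target]
        raise ValueError(
            "no treatment observed for both cell types "
            f"{c_target!r} and {control!r}; candidates were {missing}")

    deltas = []
    for s in shared:  # uniform measure over Omega
        mu_t = codes[(cell_types == c_target) & (treatments == s)].mean(0)
        mu_c = codes[(cell_types == control) & (treatments == s)].mean(0)
        deltas.append(mu_t - mu_c)
    delta = np.mean(deltas, axis=0)
    return codes[base_mask] + delta


def predict_expression(bundle, predicted_codes: np.ndarray,
                       seed: int = 0) -> np.ndarray:
    """Generate expression for predicted codes with a fitted two-stage
    bundle (or any results object exposing ``generate(codes, seed)``)."""
    predicted_codes = np.asarray(predicted_codes, float)
    if predicted_codes.shape[0] == 0:
        return np.empty((0, 0))
    return bundle.generate(codes=predicted_codes, seed=seed)


def latent_entropy(tau: np.ndarray, posterior: GaussianPosterior,
                   eps: float = 1e-12) -> float:
    """Monte-Carlo cross-entropy of code sample ``tau`` against the
    aggregate posterior mixture of a data subset.

    H{tau(Z), g(X)} = - mean_{z in tau} log (1/n) sum_i N(z; mu_i, var_i),
    log-sum-exp stabilized; posterior variances floored at ``eps``.
    """
    tau = np.atleast_2d(np.asarray(tau, float))
    if tau.shape[0] == 0:
        raise ValueError("tau sample is empty")
    means = posterior.mean
    varis = np.maximum(posterior.var, eps)
    logdet = np.log(varis).sum(axis=1)
    total = 0.0
    for start in range(0, tau.shape[0], 512):
        zz = tau[start:start + 512]
        quad = (((zz[:, None, :] - means[None, :, :]) ** 2)
                / varis[None, :, :]).sum(axis=2)
        lp = -0.5 * (quad + logdet[None, :] + tau.shape[1] * _LOG2PI)
        mx = lp.max(axis=1, keepdims=True)
        lme = np.log(np.exp(lp - mx).sum(axis=1)) + mx[:, 0] \
            - np.log(means.shape[0])
        total += lme.sum()
    return float(-total / tau.shape[0])


@dataclass
class EntropyReport:
    """Per held-out combination: H_fake, H_real and delta_H, sorted
    ascending by delta_H (low = predictable)."""

    table: pd.DataFrame

    def __str__(self):
        return self.table.to_string(index=False)


def rank_combinations_by_delta_h(grid: CombinationGrid, codes: np.ndarray,
                                 posterior: GaussianPosterior,
                                 control_map: dict | None = None
                                 ) -> EntropyReport:
    """delta_H for every held-out combination of a grid.

    ``codes``/``posterior`` cover *all* cells (aligned with the grid
    labels); arithmetic only ever uses observed cells.  ``control_map``
    optionally fixes the control cell type per held-out pair; by default
    the first other observed cell type is used.
    """
    rows = []
    obs_mask = grid.mask_observed()
    ct, tr = grid.cell_types, grid.treatments
    for c_t, d_t in grid.held_out:
        sub = (ct == c_t) & (tr == d_t)
        if not sub.any():
            raise ValueError(f"no cells for held-out pair ({c_t}, {d_t})")
        control = None
        if control_map is not None:
            control = control_map.get((c_t, d_t))
        if control is None:
            others = [c for c in np.unique(ct[obs_mask]) if c != c_t]
            control = others[0]
        tau_fake = predict_latents(codes[obs_mask], ct[obs_mask],
                                   tr[obs_mask], (c_t, d_t), control)
        tau_real = codes[sub]
        post_sub = posterior.subset(np.flatnonzero(sub))
        h_fake = latent_entropy(tau_fake, post_sub)
        h_real = latent_entropy(tau_real, post_sub)
        rows.append({"cell_type": c_t, "treatment": d_t,
                     "control": control, "H_fake": h_fake,
                     "H_real": h_real, "delta_H": h_fake - h_real})
    table = pd.DataFrame(rows).sort_values("delta_H", ignore_index=True)
    return EntropyReport(table)
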