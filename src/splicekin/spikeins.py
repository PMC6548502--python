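"""Spike-in based normalization: depth factors, cross-contamination and the
shared NB dispersion.

Labeled and unlabeled synthetic RNA spike-ins are added at constant amounts
to every sample before purification.  Their expected counts follow

    E_ij = F_j * p_ij * w_ij,   w_ij = 1 for labeled spike-ins,
                                w_ij = chi_j for unlabeled spike-ins,

where F_j is the per-sample depth / labeled-fraction factor, p_ij the
spike-in extraction probability and chi_j the cross-contamination: the
fraction of unlabeled RNA that leaks into the purified (TT-seq) fraction.
chi_j is fixed to 1 for RNA-seq samples, which capture all RNA.  Extraction
probabilities are shared across samples within a condition: each unlabeled
spike-in gets one p for RNA-seq samples and one for TT-seq samples, while a
labeled spike-in has a single p across all samples.  Counts are NB
distributed with a single dispersion theta shared by all data; that theta
is reused downstream by the kinetic fits.

Two scale conventions pin the remaining non-identifiable directions: the
geometric mean of the labeled-spike extraction probabilities is fixed at a
configured constant, and the geometric mean of the TT-seq extraction
probabilities of unlabeled spikes is tied to their RNA-seq counterpart so
that the average TT-seq depletion of unlabeled material is attributed to
chi rather than to p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from splicekin.nb import nb_loglik


class SpikeinFitError(RuntimeError):
    """Raised when the spike-in GLM does not converge; carries the last
    objective value as ``objective``."""

    def __init__(self, message, objective=float("nan")):
        super().__init__(message)
        self.objective = objective


@dataclass
class NormalizationFactors:
    """Fitted normalization: per-sample F and chi, per-spike extraction
    probabilities, and the shared NB dispersion theta."""

    factors: pd.DataFrame  # sample_id, F, chi
    extraction: pd.DataFrame  # spike_id, condition, p
    theta: float
    loglik: float


def expected_spikein_count(F, p, chi, delta):
    """Expected count of one spike-in in one sample.

    ``delta`` is 0 for a labeled spike-in and 1 for an unlabeled one; the
    unlabeled expectation carries the cross-contamination weight chi, the
    labeled one does not.  With chi = 1 (RNA-seq) the expectation is F*p
    regardless of labeling.
    """
    chi = np.asarray(chi, dtype=float)
    if np.any((chi <= 0) | (chi > 1)):
        raise ValueError("chi must lie in (0, 1]")
    delta = np.asarray(delta)
    return np.asarray(F, dtype=float) * np.asarray(p, dtype=float) * np.where(delta == 0, 1.0, chi)


def background_subtract(K, F, chi, K_rnaseq, F_rnaseq):
    """Depth-normalize a labeled-fraction count and subtract the expected
    unlabeled carry-over: ``K/F - chi * K_rnaseq / F_rnaseq``.

    The result may be negative for noisy low counts and is reported as-is.
    """
    return np.asarray(K, dtype=float) / F - np.asarray(chi, dtype=float) * np.asarray(
        K_rnaseq, dtype=float
    ) / F_rnaseq


def _unpack(x, m, n_lab, n_unlab, tt_idx, p0_labeled, theta_fixed):
    i = 0
    zF = x[i : i + m]
    i += m
    zL = x[i : i + n_lab]
    i += n_lab
    zR = x[i : i + n_unlab]
    i += n_unlab
    zT = x[i : i + n_unlab]
    i += n_unlab
    u = x[i : i + tt_idx.size]
    i += tt_idx.size
    theta = theta_fixed if theta_fixed is not None else np.exp(x[i])
    F = np.exp(zF)
    p_lab = np.exp(zL - zL.mean() + np.log(p0_labeled)) if n_lab else np.empty(0)
    p_R = np.exp(zR)
    p_T = np.exp(zT - zT.mean() + zR.mean()) if n_unlab else np.empty(0)
    chi = np.ones(m)
    chi[tt_idx] = expit(u)
    return F, p_lab, p_R, p_T, chi, theta


def _expectation(F, p_lab, p_R, p_T, chi, lab_mask, is_tt):
    n_spike, m = lab_mask.size, F.size
    E = np.empty((n_spike, m))
    # assemble row by row to keep the sharing rule explicit
    il = iu = 0
    for i in range(n_spike):
        if lab_mask[i]:
            E[i] = F * p_lab[il]
            il += 1
        else:
            p_row = np.where(is_tt, p_T[iu], p_R[iu])
            E[i] = F * p_row * np.where(is_tt, chi, 1.0)
            iu += 1
    return E


def fit_spikein_model(
    spikes: pd.DataFrame,
    design: pd.DataFrame,
    theta: float | None = None,
    p0_labeled: float = 0.5,
    max_iter: int = 500,
) -> NormalizationFactors:
    """Fit the spike-in GLM by NB maximum likelihood.

    Parameters
    ----------
    spikes
        Table with columns ``spike_id``, ``labeled`` (1 for 4sU-labeled, 0
        for unlabeled) and one count column per sample.
    design
        Sample table with ``sample_id`` and ``protocol`` in
        {"ttseq", "rnaseq"}.
    theta
        If given, the NB dispersion is held fixed instead of being
        estimated jointly.
    p0_labeled
        Scale convention: geometric mean of the labeled-spike extraction
        probabilities.
    """
    sample_ids = design["sample_id"].tolist()
    if len(sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    missing = [s for s in sample_ids if s not in spikes.columns]
    if missing:
        raise ValueError(f"spike table lacks count columns for samples: {missing}")
    K = spikes[sample_ids].to_numpy(dtype=float)
    zero_samples = [s for s, tot in zip(sample_ids, K.sum(axis=0)) if tot == 0]
    if zero_samples:
        raise ValueError(f"all-zero spike-in counts for samples: {zero_samples}")
    lab_mask = spikes["labeled"].to_numpy() == 1
    if not lab_mask.any() or lab_mask.all():
        raise ValueError("need at least one labeled and one unlabeled spike-in")
    is_tt = (design["protocol"].to_numpy() == "ttseq")
    m, n_lab, n_unlab = len(sample_ids), int(lab_mask.sum()), int((~lab_mask).sum())
    tt_idx = np.flatnonzero(is_tt)

    def negll(x):
        F, p_lab, p_R, p_T, chi, th = _unpack(x, m, n_lab, n_unlab, tt_idx, p0_labeled, theta)
        E = _expectation(F, p_lab, p_R, p_T, chi, lab_mask, is_tt)
        return -nb_loglik(K, E, th)

    # moment-based starting point
    colsum = K.sum(axis=0)
    zF0 = np.log(colsum / np.exp(np.mean(np.log(colsum))))
    x0 = np.concatenate(
        [
            zF0,
            np.log(np.maximum(K[lab_mask].mean(axis=1), 0.5)),
            np.log(np.maximum(K[~lab_mask].mean(axis=1), 0.5)),
            np.zeros(n_unlab),
            np.zeros(tt_idx.size),
            [] if theta is not None else [np.log(10.0)],
        ]
    )
    opts = {"ftol": 1e-16, "gtol": 1e-12, "maxiter": max_iter, "maxfun": 20 * max_iter * x0.size}
    res = minimize(negll, x0, method="L-BFGS-B", options=opts)
    # finite-difference noise stalls the quasi-Newton steps around 1e-6 in
    # the parameters; a derivative-free polish recovers the last digits
    polish = minimize(
        negll, res.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxfev": 40000, "adaptive": True},
    )
    if polish.fun <= res.fun:
        res = polish
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        raise SpikeinFitError("spike-in GLM did not converge", objective=float(res.fun))
    F, p_lab, p_R, p_T, chi, th = _unpack(res.x, m, n_lab, n_unlab, tt_idx, p0_labeled, theta)
    factors = pd.DataFrame({"sample_id": sample_ids, "F": F, "chi": chi})
    rows = []
    lab_ids = spikes.loc[lab_mask, "spike_id"].tolist()
    unlab_ids = spikes.loc[~lab_mask, "spike_id"].tolist()
    for sid, p in zip(lab_ids, p_lab):
        rows.append({"spike_id": sid, "condition": "all", "p": p})
    for sid, pr, pt in zip(unlab_ids, p_R, p_T):
        rows.append({"spike_id": sid, "condition": "rnaseq", "p": pr})
        rows.append({"spike_id": sid, "condition": "ttseq", "p": pt})
    return NormalizationFactors(
        factors=factors,
        extraction=pd.DataFrame(rows),
        theta=float(th),
        loglik=float(-res.fun),
    )
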