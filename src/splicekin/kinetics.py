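"""Per-bond kinetic models and their negative-binomial maximum-likelihood
fits.

Each phosphodiester bond i is modeled at steady state by first-order
kinetics ``dc/dt = alpha - beta * c``: synthesis at a constant rate alpha
(normalized counts per minute) and decay with rate beta (1/min), so the
bond half-life is ``ln 2 / beta`` and the steady-state level ``alpha /
beta``.  During a 4sU pulse of duration t the labeled bond concentration is
``(alpha/beta) (1 - exp(-t beta))`` and the pre-existing unlabeled pool
decays as ``(alpha/beta) exp(-t beta)``.  A TT-seq sample captures the
labeled pool plus a fraction chi of the unlabeled pool (cross-contamination),
an RNA-seq sample captures everything, giving expected counts

    E = F (alpha/beta) (1 + exp(-t beta) (chi - 1))   TT-seq
    E = F (alpha/beta)                                 RNA-seq

with F the per-sample depth factor.  Counts are NB distributed around E
with a dispersion shared across all bonds (fitted from spike-ins).

Two refinements of the donor and junction kinetics are also provided: a
delay model for donor bonds (transcription of the intron up to the
branchpoint takes a lag tau, then the first transesterification proceeds
with rate lambda) and a coupled two-compartment model for junction bonds
(junctions are produced by a first-order splicing process with rate
beta_spl acting on the precursor, and the spliced product decays with rate
beta_deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from splicekin.design import DesignArrays
from splicekin.nb import nb_dloglik_dmu, nb_loglik

LN2 = math.log(2.0)

# random-initialization ranges for the multistart optimizer
_ALPHA_INIT_RANGE = (1e-2, 1e3)  # normalized counts / min
_HALFLIFE_INIT_RANGE = (0.1, 1e4)  # minutes
_TAU_INIT_RANGE = (0.05, 20.0)  # minutes

DEFAULT_MIN_TOTAL_COUNT = 100


# ---------------------------------------------------------------------------
# model expectations


def expected_bond_count(alpha, beta, t, F, chi, protocol="ttseq"):
    """Expected read count of a first-order bond in one sample.

    TT-seq: ``F (alpha/beta) (1 + exp(-t beta)(chi - 1))``; RNA-seq (the
    steady state): ``F alpha / beta``.  With chi = 1 the TT-seq expectation
    collapses to the RNA-seq one for any t.
    """
    if np.any(np.asarray(beta) <= 0) or np.any(np.asarray(alpha) <= 0):
        raise ValueError("alpha and beta must be positive")
    chi = np.asarray(chi, dtype=float)
    if np.any((chi <= 0) | (chi > 1)):
        raise ValueError("chi must lie in (0, 1]")
    level = np.asarray(F, dtype=float) * np.asarray(alpha, dtype=float) / beta
    if protocol == "rnaseq":
        return level
    if protocol != "ttseq":
        raise ValueError(f"unknown protocol {protocol!r}")
    return level * (1.0 + np.exp(-np.asarray(t, dtype=float) * beta) * (chi - 1.0))


def first_order_expectation(alpha: float, beta: float, d: DesignArrays) -> np.ndarray:
    """Vector of expected counts across all samples of a design."""
    level = d.F * alpha / beta
    out = level.copy()
    tt = d.is_ttseq
    out[tt] = level[tt] * (1.0 + np.exp(-d.t[tt] * beta) * (d.chi[tt] - 1.0))
    return out


def delay_expectation(alpha: float, tau: float, lam: float, d: DesignArrays) -> np.ndarray:
    """Expected counts under the delayed donor-bond model.

    A donor bond exists from the moment it is synthesized but cannot be
    cleaved before the intron is transcribed up to the branchpoint, a lag
    tau; cleavage then proceeds with rate lam.  Bond lifetimes are therefore
    tau plus an exponential, with survival S(u) = 1 for u < tau and
    exp(-(u - tau) lam) after.  The labeled pool after a pulse of length t
    is alpha * integral_0^t S(u) du:

        alpha * t                                       t <= tau
        alpha * (tau + (1 - exp(-(t - tau) lam)) / lam) t > tau

    ramping linearly while cleavage is blocked and saturating at the steady
    state alpha (tau + 1/lam).  The unlabeled pool is the complement to the
    steady state, and TT-seq mixes the two with weight chi on the unlabeled
    pool exactly as in the first-order model.  tau = 0 recovers first-order
    kinetics with beta = lam.
    """
    level = alpha * (tau + 1.0 / lam)
    labeled = np.where(
        d.t <= tau,
        alpha * d.t,
        alpha * (tau + (1.0 - np.exp(-np.maximum(d.t - tau, 0.0) * lam)) / lam),
    )
    out = d.F * level * np.ones(d.n_samples)
    tt = d.is_ttseq
    out[tt] = d.F[tt] * (labeled[tt] + d.chi[tt] * (level - labeled[tt]))
    return out


def _coupled_labeled(alpha: float, a: float, b: float, t: np.ndarray) -> np.ndarray:
    """Labeled product concentration of the precursor -> product chain.

    Precursor is synthesized at alpha and converted with rate a; product
    decays with rate b.  The closed form is symmetric in (a, b); a series
    limit is used when the two rates nearly coincide.
    """
    level = alpha / b
    if abs(a - b) <= 1e-8 * max(a, b):
        r = 0.5 * (a + b)
        return level * (1.0 - np.exp(-r * t) * (1.0 + r * t))
    return level * (1.0 - (b * np.exp(-a * t) - a * np.exp(-b * t)) / (b - a))


def coupled_expectation(
    alpha: float, beta_spl: float, beta_deg: float, d: DesignArrays
) -> np.ndarray:
    """Expected junction counts under the coupled splicing->decay model."""
    level = alpha / beta_deg
    out = d.F * level * np.ones(d.n_samples)
    tt = d.is_ttseq
    labeled = _coupled_labeled(alpha, beta_spl, beta_deg, d.t[tt])
    out[tt] = d.F[tt] * (labeled + d.chi[tt] * (level - labeled))
    return out


# ---------------------------------------------------------------------------
# estimates


@dataclass
class RateEstimate:
    """First-order fit of one bond: synthesis rate alpha (normalized
    counts/min), decay rate beta (1/min), half-life ln2/beta (min)."""

    bond_id: str
    bond_type: str
    alpha: float
    beta: float
    n_inits_used: int
    objective: float
    status: str = "ok"

    @property
    def half_life(self) -> float:
        return LN2 / self.beta

    @property
    def steady_state(self) -> float:
        return self.alpha / self.beta


@dataclass
class DelayEstimate:
    """Delay-model fit of a donor bond: lag tau (min) for intron
    transcription up to the branchpoint, then cleavage at rate lam."""

    bond_id: str
    alpha: float
    tau: float
    lam: float
    n_inits_used: int
    objective: float
    status: str = "ok"

    @property
    def half_life(self) -> float:
        """Apparent donor half-life: delay plus first-step half-time."""
        return self.tau + LN2 / self.lam


@dataclass
class CoupledEstimate:
    """Coupled fit of a junction bond: precursor feed alpha, splicing rate
    beta_spl and product degradation rate beta_deg."""

    junction_id: str
    alpha_precursor: float
    beta_spl: float
    beta_deg: float
    n_inits_used: int
    objective: float
    status: str = "ok"


# ---------------------------------------------------------------------------
# first-order fit (analytic gradient, multistart, median across starts)


# log-parameters are kept inside |x| < _LOG_WALL by a smooth quadratic
# penalty; e^40 is far beyond any biologically or numerically meaningful
# rate, so the wall never binds at a genuine optimum.
_LOG_WALL = 40.0


def _wall_penalty(x):
    over = np.maximum(np.abs(np.asarray(x, dtype=float)) - _LOG_WALL, 0.0)
    return 1e6 * float(np.sum(over**2)), 2e6 * over * np.sign(x)


def _neg_loglik_first_order(x, k, d: DesignArrays, theta):
    # parameterized as (log steady-state level, log beta): the RNA-seq
    # samples pin the level and the time-course shape pins beta, so the two
    # coordinates are nearly orthogonal in the likelihood, unlike
    # (log alpha, log beta) which share a strong ridge along alpha/beta.
    pen, dpen = _wall_penalty(x)
    ll_, lb = np.clip(x, -_LOG_WALL, _LOG_WALL)
    level0, beta = math.exp(ll_), math.exp(lb)
    level = d.F * level0
    mu = level.copy()
    tt = d.is_ttseq
    e = np.exp(-d.t[tt] * beta)
    mu[tt] = level[tt] * (1.0 + e * (d.chi[tt] - 1.0))
    ll = nb_loglik(k, mu, theta)
    g = nb_dloglik_dmu(k, mu, theta)
    # d mu / d log level = mu; d mu / d log beta = -F*level*t*beta*e*(chi-1)
    dmu_lb = np.zeros_like(mu)
    dmu_lb[tt] = -level[tt] * d.t[tt] * beta * e * (d.chi[tt] - 1.0)
    return -ll + pen, np.array([-np.sum(g * mu), -np.sum(g * dmu_lb)]) + dpen


def fit_bond_first_order(
    k: np.ndarray,
    d: DesignArrays,
    theta: float,
    rng: np.random.Generator,
    n_starts: int = 10,
    bond_id: str = "",
    bond_type: str = "",
) -> RateEstimate:
    """Fit (alpha, beta) of one bond by NB maximum likelihood.

    The optimizer (BFGS on log steady-state level and log beta) is started
    from ``n_starts`` independent random (alpha, half-life) draws.  The
    likelihood is flat in beta outside the window resolved by the labeling
    durations, so starts landing on those plateaus cannot move; the
    reported alpha and beta are therefore the element-wise medians over the
    starts that reached the consensus optimum (within one log-likelihood
    unit of the best run).  When no start is better than the rest the data
    carry no rate information and the median over all runs is reported.
    Deterministic given the generator state.
    """
    k = np.asarray(k, dtype=float)
    la0 = rng.uniform(*np.log(_ALPHA_INIT_RANGE), size=n_starts)
    lh0 = rng.uniform(*np.log(_HALFLIFE_INIT_RANGE), size=n_starts)
    lb0 = math.log(LN2) - lh0
    sols, funs = [], []
    for la, lb in zip(la0, lb0):
        res = minimize(
            _neg_loglik_first_order,
            np.array([la - lb, lb]),  # (log level, log beta) coordinates
            args=(k, d, theta),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-8, "maxiter": 1000},
        )
        if np.all(np.isfinite(res.x)) and np.isfinite(res.fun):
            sols.append(res.x)
            funs.append(res.fun)
    if not sols:
        return RateEstimate(bond_id, bond_type, math.nan, math.nan, 0, math.nan, "failed")
    sols, funs = np.asarray(sols), np.asarray(funs)
    near_best = funs <= funs.min() + 1.0
    ll_med, lb_med = np.median(sols[near_best], axis=0)
    obj, _ = _neg_loglik_first_order((ll_med, lb_med), k, d, theta)
    return RateEstimate(
        bond_id,
        bond_type,
        math.exp(ll_med + lb_med),
        math.exp(lb_med),
        int(near_best.sum()),
        -obj,
    )


# ---------------------------------------------------------------------------
# delay and coupled fits (numeric gradients, best-of-starts)


def _fit_multistart(objective, inits, max_retry_rounds=3, rng=None, resample=None):
    best, n_ok = None, 0
    rounds = 0
    while True:
        for x0 in inits:
            res = minimize(objective, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": 1000})
            if np.all(np.isfinite(res.x)) and np.isfinite(res.fun):
                n_ok += 1
                if best is None or res.fun < best.fun:
                    best = res
        if best is not None or rounds >= max_retry_rounds or resample is None:
            break
        rounds += 1
        inits = resample()
    return best, n_ok


def fit_bond_delay(
    k: np.ndarray,
    d: DesignArrays,
    theta: float,
    rng: np.random.Generator,
    n_starts: int = 10,
    bond_id: str = "",
) -> DelayEstimate:
    """Fit the delayed donor model (alpha, tau, lam) by NB ML.

    tau and lam are weakly identifiable from count data alone: curves with a
    longer delay and faster cleavage are close to curves with a shorter
    delay and slower cleavage.  The apparent half-life tau + ln2/lam is far
    better determined than either parameter.
    """
    k = np.asarray(k, dtype=float)

    # optimized over (log steady level, log tau, log lam); the RNA-seq
    # samples pin the level, decoupling it from the rate parameters
    def obj(x):
        pen, _ = _wall_penalty(x)
        lvl, tau, lam = np.exp(np.clip(x, -_LOG_WALL, _LOG_WALL))
        alpha = lvl / (tau + 1.0 / lam)
        return -nb_loglik(k, delay_expectation(alpha, tau, lam, d), theta) + pen

    def draw():
        la = rng.uniform(*np.log(_ALPHA_INIT_RANGE), size=n_starts)
        ltau = rng.uniform(*np.log(_TAU_INIT_RANGE), size=n_starts)
        llam = math.log(LN2) - rng.uniform(*np.log(_HALFLIFE_INIT_RANGE), size=n_starts)
        lvl = la + np.log(np.exp(ltau) + np.exp(-llam))
        return np.column_stack([lvl, ltau, llam])

    best, n_ok = _fit_multistart(obj, draw(), rng=rng, resample=draw)
    if best is None:
        return DelayEstimate(bond_id, math.nan, math.nan, math.nan, 0, math.nan, "failed")
    lvl, tau, lam = np.exp(best.x)
    return DelayEstimate(bond_id, lvl / (tau + 1.0 / lam), tau, lam, n_ok, -best.fun)


def fit_bond_coupled(
    k: np.ndarray,
    d: DesignArrays,
    theta: float,
    rng: np.random.Generator,
    n_starts: int = 10,
    junction_id: str = "",
    precursor: RateEstimate | None = None,
) -> CoupledEstimate:
    """Fit the coupled junction model (alpha, beta_spl, beta_deg) by NB ML.

    Without a precursor estimate all three parameters are free; the
    labeled curve is then symmetric in (beta_spl, beta_deg) and the two
    fitted rates form an unordered pair, reported with the faster one as
    beta_spl (splicing is typically much faster than product decay).  When
    a matched precursor (acceptor) estimate is given, its decay rate --
    the rate at which the precursor is cleared by splicing -- is taken as
    beta_spl and held fixed, which removes the symmetry degeneracy and
    anchors the feed rate alpha = level * beta_deg.
    """
    k = np.asarray(k, dtype=float)
    fixed_a = precursor.beta if (precursor is not None and np.isfinite(precursor.beta)) else None

    # optimized over log (steady level, a, b) with level = alpha / b
    if fixed_a is None:

        def obj(x):
            pen, _ = _wall_penalty(x)
            lvl, a, b = np.exp(np.clip(x, -_LOG_WALL, _LOG_WALL))
            return -nb_loglik(k, coupled_expectation(lvl * b, a, b, d), theta) + pen

        def draw():
            la = rng.uniform(*np.log(_ALPHA_INIT_RANGE), size=n_starts)
            lb = math.log(LN2) - rng.uniform(*np.log(_HALFLIFE_INIT_RANGE), size=n_starts)
            return np.column_stack(
                [
                    la - lb,
                    math.log(LN2) - rng.uniform(*np.log(_HALFLIFE_INIT_RANGE), size=n_starts),
                    lb,
                ]
            )

    else:

        def obj(x):
            pen, _ = _wall_penalty(x)
            lvl, b = np.exp(np.clip(x, -_LOG_WALL, _LOG_WALL))
            return -nb_loglik(k, coupled_expectation(lvl * b, fixed_a, b, d), theta) + pen

        def draw():
            la = rng.uniform(*np.log(_ALPHA_INIT_RANGE), size=n_starts)
            lb = math.log(LN2) - rng.uniform(*np.log(_HALFLIFE_INIT_RANGE), size=n_starts)
            return np.column_stack([la - lb, lb])

    best, n_ok = _fit_multistart(obj, draw(), rng=rng, resample=draw)
    if best is None:
        return CoupledEstimate(junction_id, math.nan, math.nan, math.nan, 0, math.nan, "failed")
    if fixed_a is None:
        lvl, a, b = np.exp(best.x)
        spl, deg = max(a, b), min(a, b)
    else:
        lvl, deg = np.exp(best.x)
        spl = fixed_a
    # the labeled curve is symmetric in the two rates but the feed is not:
    # alpha = steady level * degradation rate of the chosen assignment
    return CoupledEstimate(junction_id, lvl * deg, spl, deg, n_ok, -best.fun)


# ---------------------------------------------------------------------------
# table-level fitting


def bond_matrix(counts: pd.DataFrame, sample_order) -> pd.DataFrame:
    """Pivot a long BondCounts table into a bonds x samples count matrix.

    ``counts`` has columns intron_id, sample_id, donor, acceptor, junction;
    the result is indexed by ``"<intron_id>:<bond_type>"``.
    """
    long = counts.melt(
        id_vars=["intron_id", "sample_id"],
        value_vars=["donor", "acceptor", "junction"],
        var_name="bond_type",
        value_name="count",
    )
    long["bond_id"] = long["intron_id"].astype(str) + ":" + long["bond_type"]
    wide = long.pivot_table(index="bond_id", columns="sample_id", values="count", aggfunc="sum")
    missing = [s for s in sample_order if s not in wide.columns]
    if missing:
        raise ValueError(f"counts missing for samples: {missing}")
    return wide[list(sample_order)]


def fit_rates(
    counts: pd.DataFrame,
    d: DesignArrays,
    theta: float,
    model: str = "first_order",
    min_total_count: int = DEFAULT_MIN_TOTAL_COUNT,
    seed: int = 0,
    n_starts: int = 10,
    precursors: dict[str, RateEstimate] | None = None,
) -> pd.DataFrame:
    """Fit every bond of a bonds x samples count matrix.

    Bonds with fewer than ``min_total_count`` reads summed over all samples
    are excluded, mirroring the coverage filter used when processing the
    real time series.  Rows of ``counts`` must align with ``d`` columns.
    """
    if model not in {"first_order", "delay", "coupled"}:
        raise ValueError(f"unknown model {model!r}")
    mat = counts.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for bond_id, k in zip(counts.index, mat):
        if k.sum() < min_total_count:
            continue
        child = np.random.default_rng(rng.integers(2**31))
        if model == "first_order":
            bt = bond_id.rsplit(":", 1)[-1] if ":" in str(bond_id) else ""
            est = fit_bond_first_order(k, d, theta, child, n_starts, str(bond_id), bt)
            rows.append(
                {
                    "bond_id": bond_id,
                    "bond_type": est.bond_type,
                    "alpha": est.alpha,
                    "beta": est.beta,
                    "half_life_min": LN2 / est.beta if est.status == "ok" else math.nan,
                    "model": model,
                    "status": est.status,
                    "n_inits_used": est.n_inits_used,
                    "objective": est.objective,
                }
            )
        elif model == "delay":
            est = fit_bond_delay(k, d, theta, child, n_starts, str(bond_id))
            rows.append(
                {
                    "bond_id": bond_id,
                    "bond_type": "donor",
                    "alpha": est.alpha,
                    "tau": est.tau,
                    "lam": est.lam,
                    "half_life_min": est.half_life if est.status == "ok" else math.nan,
                    "model": model,
                    "status": est.status,
                    "n_inits_used": est.n_inits_used,
                    "objective": est.objective,
                }
            )
        else:
            pre = (precursors or {}).get(str(bond_id))
            est = fit_bond_coupled(k, d, theta, child, n_starts, str(bond_id), pre)
            rows.append(
                {
                    "bond_id": bond_id,
                    "bond_type": "junction",
                    "alpha": est.alpha_precursor,
                    "beta_spl": est.beta_spl,
                    "beta_deg": est.beta_deg,
                    "half_life_min": LN2 / est.beta_deg if est.status == "ok" else math.nan,
                    "model": model,
                    "status": est.status,
                    "n_inits_used": est.n_inits_used,
                    "objective": est.objective,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "bond_id", "bond_type", "alpha", "beta", "half_life_min",
                "model", "status", "n_inits_used", "objective",
            ]
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# derived quantities


def derive_kinetic_quantities(estimate: RateEstimate) -> dict:
    """Half-life and steady-state level implied by a first-order fit."""
    return {
        "half_life_min": LN2 / estimate.beta,
        "steady_state": estimate.alpha / estimate.beta,
    }


def select_major_isoform(tpm: pd.DataFrame, gene_map: pd.Series) -> pd.Series:
    """Major isoform per gene: maximal mean TPM across RNA-seq samples.

    ``tpm`` is isoform x sample; ``gene_map`` maps isoform id -> gene id.
    Ties break lexicographically by isoform id.  Genes without isoform rows
    are simply absent from the result.
    """
    means = tpm.mean(axis=1)
    df = pd.DataFrame({"gene": gene_map.reindex(means.index), "mean_tpm": means})
    df = df.dropna(subset=["gene"]).reset_index(names="isoform")
    df = df.sort_values(["gene", "mean_tpm", "isoform"], ascending=[True, False, True])
    out = df.groupby("gene", sort=True).first()["isoform"]
    out.name = "major_isoform"
    return out


def relative_uncertainty(rates) -> float:
    """Multiplicative uncertainty of a group of rates sharing a true value.

    exp(sd(log rates) / sqrt(n)) with the sample standard deviation; 1.0 for
    identical rates, NaN for singleton groups, and invariant to a common
    scaling of the group.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        return math.nan
    logs = np.log(rates)
    return float(np.exp(np.std(logs, ddof=1) / math.sqrt(rates.size)))
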