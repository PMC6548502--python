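"""Sequence determinants of bond half-life: single-nucleotide effects,
octamer (putative regulatory motif) effects, and PWM matching.

The single-nucleotide model regresses log-transformed half-life on the
identity of each of the 20 nucleotides upstream and downstream of the
donor site, the acceptor site and the branchpoint, coded relative to the
consensus sequence so that a coefficient reads as the effect of
substituting the consensus base.  An L1 (Lasso) stage selects informative
positions (largest penalty within one standard error of the CV-minimal
MSE, 10-fold); positions whose every substitution coefficient is zero are
dropped and the survivors are refit by ordinary least squares together
with three GC-content covariates.

The octamer model counts all candidate 8-mers (allowing mismatches) in
four intronic regions -- 15-100 nt downstream of the donor, 100 nt
upstream of the branchpoint, between the branchpoint and 5 nt upstream of
the acceptor, and 5-100 nt upstream of the acceptor, each cropped to the
intron -- and uses log2(count + 1) covariates in a two-stage Lasso
(per-region 5-fold selection, then a joint 10-fold refinement with the
single-nucleotide features, per-region GC, intron length and a
first-intron flag).

PWM matching scores each octamer against a position weight matrix as the
probability of its best alignment divided by the highest probability any
sequence could achieve (relative PWM score), keeping hits in the top 5%
per PWM with a score of at least 0.9.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import KFold

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

WINDOW = 20
OCTAMER_LENGTH = 8
REGIONS = ("donor_downstream", "branchpoint_upstream", "branchpoint_to_acceptor", "acceptor_upstream")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in BASES)
    return (seq.count("G") + seq.count("C")) / acgt if acgt else math.nan


@dataclass
class SpliceSiteSequenceContext:
    """RNA-sense sequence context of one intron.

    ``windows`` maps the six window names (donor/acceptor/branchpoint x
    upstream/downstream) to 20-nt strings; position 0 of each downstream
    window is the site base itself (first intronic base at the donor, the
    branchpoint adenosine, first exonic base at the acceptor).
    ``intron_seq`` is the full RNA-sense intron with ``bp_offset`` the
    0-based branchpoint index within it.
    """

    intron_id: str
    windows: dict
    intron_seq: str
    bp_offset: int
    gc_intron: float
    gc_donor: float
    gc_acceptor: float
    intron_length: int
    first_intron: bool = False

    def region_sequences(self) -> dict:
        """The four intronic octamer-search regions, cropped to the intron."""
        L = len(self.intron_seq)
        bp = self.bp_offset
        return {
            "donor_downstream": self.intron_seq[15:min(100, L)],
            "branchpoint_upstream": self.intron_seq[max(0, bp - 100):bp],
            "branchpoint_to_acceptor": self.intron_seq[bp + 1:max(bp + 1, L - 5)],
            "acceptor_upstream": self.intron_seq[max(0, L - 100):L - 5],
        }


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Upper-case slice of a contig from a pyfaidx.Fasta or plain mapping."""
    seq = genome[chrom]
    piece = seq[start:end]
    return str(piece).upper()


def extract_context(genome, intron, branchpoint: int, first_intron: bool = False):
    """Build the sequence context of an intron from an indexed genome.

    ``branchpoint`` is the genomic (0-based) position of the branchpoint
    adenosine inside the intron.  Windows run off the contig raise a
    ``ValueError`` naming the intron.
    """
    iv = intron.interval
    if not (iv.start <= branchpoint < iv.end):
        raise ValueError(f"branchpoint {branchpoint} outside intron {intron.id}")
    contig_len = len(genome[iv.chrom])
    if iv.start - WINDOW < 0 or iv.end + WINDOW > contig_len:
        raise ValueError(f"window off contig for intron {intron.id}")
    plus = iv.strand == "+"

    def window(center: int, side: str) -> str:
        # transcript-sense 20-mer before (upstream) or from (downstream) a base
        if plus:
            s = _fetch(genome, iv.chrom, center - WINDOW, center) if side == "up" else _fetch(
                genome, iv.chrom, center, center + WINDOW
            )
            return s
        if side == "up":
            return reverse_complement(_fetch(genome, iv.chrom, center + 1, center + 1 + WINDOW))
        return reverse_complement(_fetch(genome, iv.chrom, center - WINDOW + 1, center + 1))

    donor = intron.donor_site
    acceptor = intron.acceptor_site
    exon_after = acceptor + 1 if plus else acceptor - 1
    windows = {
        "donor_up": window(donor, "up"),
        "donor_down": window(donor, "down"),
        "acceptor_up": window(exon_after, "up"),
        "acceptor_down": window(exon_after, "down"),
        "branchpoint_up": window(branchpoint, "up"),
        "branchpoint_down": window(branchpoint, "down"),
    }
    intron_seq = _fetch(genome, iv.chrom, iv.start, iv.end)
    if not plus:
        intron_seq = reverse_complement(intron_seq)
        bp_offset = iv.end - 1 - branchpoint
    else:
        bp_offset = branchpoint - iv.start
    return SpliceSiteSequenceContext(
        intron_id=intron.id,
        windows=windows,
        intron_seq=intron_seq,
        bp_offset=bp_offset,
        gc_intron=gc_fraction(intron_seq),
        gc_donor=gc_fraction(windows["donor_up"] + windows["donor_down"]),
        gc_acceptor=gc_fraction(windows["acceptor_up"] + windows["acceptor_down"]),
        intron_length=iv.length,
        first_intron=first_intron,
    )


# ---------------------------------------------------------------------------
# single-nucleotide model

_CANONICAL = {("donor_down", 0): "G", ("donor_down", 1): "T", ("acceptor_up", 18): "A", ("acceptor_up", 19): "G"}


def _position_labels():
    return [(w, i) for w in ("donor_up", "donor_down", "acceptor_up", "acceptor_down", "branchpoint_up", "branchpoint_down") for i in range(WINDOW)]


def consensus_sequence(contexts) -> dict:
    """Modal base per window position; ties resolved toward the canonical
    splice-site dinucleotides (GT..AG) where applicable, else
    alphabetically."""
    cons = {}
    for w, i in _position_labels():
        counts = {b: 0 for b in BASES}
        for c in contexts:
            b = c.windows[w][i]
            if b in counts:
                counts[b] += 1
        top = max(counts.values())
        tied = [b for b in BASES if counts[b] == top]
        if len(tied) > 1 and (w, i) in _CANONICAL and _CANONICAL[(w, i)] in tied:
            cons[(w, i)] = _CANONICAL[(w, i)]
        else:
            cons[(w, i)] = tied[0]
    return cons


def _single_nt_design(contexts, cons):
    """Indicator columns (3 per position) relative to consensus, plus a
    validity mask excluding introns with N in any window."""
    labels, cols = [], []
    valid = np.ones(len(contexts), dtype=bool)
    for j, c in enumerate(contexts):
        if any("N" in c.windows[w] for w in c.windows):
            valid[j] = False
    for w, i in _position_labels():
        ref = cons[(w, i)]
        for b in BASES:
            if b == ref:
                continue
            labels.append((w, i, b))
            cols.append([1.0 if c.windows[w][i] == b else 0.0 for c in contexts])
    X = np.array(cols).T
    gc = np.array([[c.gc_intron, c.gc_donor, c.gc_acceptor] for c in contexts])
    return X, gc, labels, valid


def _lasso_one_se(X, y, n_folds, seed):
    """Lasso path with K-fold CV; returns the largest penalty whose mean CV
    MSE is within one standard error of the minimum."""
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lcv = LassoCV(alphas=60, cv=cv, max_iter=50000).fit(X, y)
    mse = lcv.mse_path_.mean(axis=1)
    se = lcv.mse_path_.std(axis=1, ddof=1) / math.sqrt(n_folds)
    i_min = int(np.argmin(mse))
    threshold = mse[i_min] + se[i_min]
    candidates = np.flatnonzero(mse <= threshold)
    # alphas_ are in decreasing order: the smallest index is the largest penalty
    return float(lcv.alphas_[candidates.min()]), lcv


@dataclass
class SequenceEffectModel:
    """Selected positions and per-substitution effects on the (log-scale)
    response, relative to the consensus base."""

    consensus: dict
    coefficients: pd.DataFrame  # window, position, base, coef
    gc_coefficients: np.ndarray
    gc_means: np.ndarray
    intercept: float
    retained_positions: list
    r_squared: float
    mult_median_error: float
    labels: list = field(default_factory=list)

    def predict(self, contexts) -> np.ndarray:
        X, gc, labels, _ = _single_nt_design(contexts, self.consensus)
        coef = np.zeros(len(labels))
        lookup = {
            (r.window, r.position, r.base): r.coef for r in self.coefficients.itertuples()
        }
        for j, lab in enumerate(labels):
            coef[j] = lookup.get(lab, 0.0)
        return self.intercept + X @ coef + (gc - self.gc_means) @ self.gc_coefficients


def mult_median_error(y_log, yhat_log) -> float:
    """Median multiplicative error on the natural scale,
    median(exp(|log(y / yhat)|)); 1.0 for perfect prediction."""
    return float(np.median(np.exp(np.abs(np.asarray(y_log) - np.asarray(yhat_log)))))


def fit_single_nt_model(contexts, response, seed: int = 0) -> SequenceEffectModel:
    """Two-stage single-nucleotide fit (see module docstring).

    ``response`` is the log half-life (or any log-scale quantity) aligned
    with ``contexts``.  Introns containing N in a window are excluded.
    """
    y = np.asarray(response, dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant response")
    cons = consensus_sequence(contexts)
    X, gc, labels, valid = _single_nt_design(contexts, cons)
    X, gc, y = X[valid], gc[valid], y[valid]
    gc_means = gc.mean(axis=0)
    gc_c = gc - gc_means
    Xfull = np.hstack([X, gc_c])
    alpha_1se, _ = _lasso_one_se(Xfull, y, n_folds=10, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lasso = Lasso(alpha=alpha_1se, max_iter=50000).fit(Xfull, y)
    nt_coef = lasso.coef_[: len(labels)]
    by_pos = {}
    for j, (w, i, b) in enumerate(labels):
        by_pos.setdefault((w, i), []).append(nt_coef[j])
    retained = sorted(pos for pos, cs in by_pos.items() if any(c != 0.0 for c in cs))
    keep = [j for j, (w, i, b) in enumerate(labels) if (w, i) in set(retained)]
    Xr = np.hstack([X[:, keep], gc_c])
    ols = LinearRegression().fit(Xr, y)
    yhat = ols.predict(Xr)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rows = []
    for jj, j in enumerate(keep):
        w, i, b = labels[j]
        rows.append({"window": w, "position": i, "base": b, "coef": ols.coef_[jj]})
    return SequenceEffectModel(
        consensus=cons,
        coefficients=pd.DataFrame(rows, columns=["window", "position", "base", "coef"]),
        gc_coefficients=ols.coef_[len(keep):],
        gc_means=gc_means,
        intercept=float(ols.intercept_),
        retained_positions=retained,
        r_squared=1.0 - ss_res / ss_tot,
        mult_median_error=mult_median_error(y, yhat),
        labels=labels,
    )


# ---------------------------------------------------------------------------
# octamer counting and model


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def count_octamers(region_sequence: str, octamer: str, max_mismatch: int = 2) -> int:
    """Offsets at which ``octamer`` matches with at most ``max_mismatch``
    Hamming mismatches; overlapping offsets all count.  N never matches."""
    if len(octamer) != OCTAMER_LENGTH:
        raise ValueError("octamer must have length 8")
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    n = len(region_sequence) - OCTAMER_LENGTH + 1
    if n <= 0:
        return 0
    enc = _encode(region_sequence.upper())
    oct_enc = _encode(octamer.upper())
    windows = np.lib.stride_tricks.sliding_window_view(enc, OCTAMER_LENGTH)
    mism = np.sum((windows != oct_enc) | (windows < 0), axis=1)
    return int(np.sum(mism <= max_mismatch))


def count_octamer_matrix(sequences, octamers, max_mismatch: int = 2) -> np.ndarray:
    """Count matrix (len(sequences) x len(octamers)) with mismatches."""
    oct_enc = np.stack([_encode(o.upper()) for o in octamers])
    out = np.zeros((len(sequences), len(octamers)), dtype=np.int32)
    for r, seq in enumerate(sequences):
        if len(seq) < OCTAMER_LENGTH:
            continue
        enc = _encode(seq.upper())
        windows = np.lib.stride_tricks.sliding_window_view(enc, OCTAMER_LENGTH)
        bad = windows < 0
        # mismatches of every window against every octamer
        mism = (windows[:, None, :] != oct_enc[None, :, :]) | bad[:, None, :]
        out[r] = np.sum(mism.sum(axis=2) <= max_mismatch, axis=0)
    return out


def observed_octamers(sequences, min_count: int = 1) -> list:
    """Distinct exact 8-mers present in the sequences (desk-scale candidate
    vocabulary when scanning all 65,536 octamers is not warranted)."""
    seen: dict[str, int] = {}
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - OCTAMER_LENGTH + 1):
            o = s[i:i + OCTAMER_LENGTH]
            if "N" not in o:
                seen[o] = seen.get(o, 0) + 1
    return sorted(o for o, c in seen.items() if c >= min_count)


@dataclass
class OctamerModel:
    """Two-stage octamer selection with the variance-explained ledger."""

    region_selected: dict  # region -> list of octamers kept by stage 1
    joint_coefficients: pd.DataFrame  # feature, group, coef
    intercept: float
    r_squared_joint: float
    variance_ledger: pd.DataFrame  # feature group, individual R2, drop-one loss


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot


def _lasso_min(X, y, n_folds, seed):
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lcv = LassoCV(alphas=40, cv=cv, max_iter=50000).fit(X, y)
    return lcv


def fit_octamer_model(
    contexts,
    response,
    octamers=None,
    max_mismatch: int = 2,
    single_nt_model: SequenceEffectModel | None = None,
    seed: int = 0,
) -> OctamerModel:
    """Per-region Lasso selection of octamers, then a joint Lasso
    refinement over all selected octamers plus single-nucleotide
    predictions, per-region GC, intron length and the first-intron flag.

    ``octamers`` defaults to the 8-mers observed in the regions.  Features
    are standardized before the L1 stages.  The variance ledger reports,
    per feature group, the variance explained by that group alone and the
    drop in joint variance explained when the group is removed.
    """
    y = np.asarray(response, dtype=float)
    regions = {r: [] for r in REGIONS}
    for c in contexts:
        seqs = c.region_sequences()
        for r in REGIONS:
            regions[r].append(seqs[r])
    if octamers is None:
        octamers = observed_octamers([s for seqs in regions.values() for s in seqs])
    groups: dict[str, np.ndarray] = {}
    selected: dict[str, list] = {}
    empty = [r for r in REGIONS if all(len(s) < OCTAMER_LENGTH for s in regions[r])]
    for r in empty:
        warnings.warn(f"region {r} empty for all introns; omitted")
    for r in REGIONS:
        if r in empty:
            selected[r] = []
            continue
        counts = np.log2(count_octamer_matrix(regions[r], octamers, max_mismatch) + 1.0)
        sd = counts.std(axis=0)
        usable = sd > 0
        Xr = (counts[:, usable] - counts[:, usable].mean(axis=0)) / sd[usable]
        names = [o for o, u in zip(octamers, usable) if u]
        lcv = _lasso_min(Xr, y, n_folds=5, seed=seed)
        nz = np.flatnonzero(lcv.coef_)
        selected[r] = [names[j] for j in nz]
        if len(nz):
            groups[f"octamers_{r}"] = Xr[:, nz]
    if single_nt_model is not None:
        groups["single_nt"] = single_nt_model.predict(contexts)[:, None]
    gc_cols = np.array(
        [
            [gc_fraction(s) if s else 0.0 for s in (regions[r][j] for r in REGIONS)]
            for j in range(len(contexts))
        ]
    )
    covar = np.column_stack(
        [
            gc_cols,
            [c.gc_intron for c in contexts],
            [math.log(c.intron_length) for c in contexts],
            [1.0 if c.first_intron else 0.0 for c in contexts],
        ]
    )
    groups["covariates"] = covar
    names_all, blocks = [], []
    for gname, block in groups.items():
        blocks.append(np.asarray(block, dtype=float))
        n_cols = blocks[-1].shape[1]
        if gname.startswith("octamers_"):
            r = gname.split("octamers_")[1]
            names_all += [(gname, o) for o in selected[r]]
        else:
            names_all += [(gname, f"{gname}_{i}") for i in range(n_cols)]
    X = np.hstack(blocks)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    joint = _lasso_min(Xs, y, n_folds=10, seed=seed + 1)
    r2_joint = _r2(y, joint.predict(Xs))
    rows = []
    col_groups = np.array([g for g, _ in names_all])
    for gname in groups:
        mask = col_groups == gname
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            indiv = _r2(y, LinearRegression().fit(Xs[:, mask], y).predict(Xs[:, mask]))
            if mask.all():
                drop = r2_joint
            else:
                sub = _lasso_min(Xs[:, ~mask], y, n_folds=10, seed=seed + 2)
                drop = r2_joint - _r2(y, sub.predict(Xs[:, ~mask]))
        rows.append({"feature_group": gname, "individual_r2": indiv, "drop_one_loss": drop})
    coef_rows = [
        {"group": g, "feature": f, "coef": c}
        for (g, f), c in zip(names_all, joint.coef_)
    ]
    return OctamerModel(
        region_selected=selected,
        joint_coefficients=pd.DataFrame(coef_rows),
        intercept=float(joint.intercept_),
        r_squared_joint=r2_joint,
        variance_ledger=pd.DataFrame(rows),
    )


def fit_yield_sequence_model(
    contexts, etas, epsilon: float = 1e-3, seed: int = 0
) -> SequenceEffectModel:
    """Single-nucleotide model with splicing yield as the response.

    Yields are log-transformed after flooring at ``epsilon`` (estimated
    yields can be zero or negative when junction fits fail or noise pushes
    the ratio below zero).  Coefficients then read as multiplicative
    effects on yield of substituting the consensus base.
    """
    y = np.log(np.maximum(np.asarray(etas, dtype=float), epsilon))
    return fit_single_nt_model(contexts, y, seed=seed)


# ---------------------------------------------------------------------------
# PWM matching


def rpm_score(octamer: str, pwm: np.ndarray) -> float:
    """Relative PWM score of an octamer against a probability matrix.

    ``pwm`` is (length, 4) over A, C, G, T with positive entries.  The
    score is the probability of the octamer's best alignment divided by
    the highest probability achievable by any sequence (so the consensus
    of an equal-length PWM scores 1).  If the PWM is longer than 8 the
    octamer is padded with N on both sides (one extra on the right for odd
    differences); an N contributes the column maximum, i.e. a neutral
    factor.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4 or pwm.shape[0] < 5:
        raise ValueError("pwm must be (length >= 5, 4)")
    if np.any(pwm <= 0):
        raise ValueError("pwm columns must be strictly positive")
    L = pwm.shape[0]
    col_max = pwm.max(axis=1)
    denom = float(np.prod(col_max))
    seq = octamer.upper()
    if L > len(seq):
        pad = L - len(seq)
        seq = "N" * (pad // 2) + seq + "N" * (pad - pad // 2)
    best = 0.0
    for off in range(len(seq) - L + 1):
        prob = 1.0
        for j in range(L):
            b = seq[off + j]
            prob *= col_max[j] if b == "N" else pwm[j, _BASE_INDEX[b]]
        best = max(best, prob)
    return best / denom


def match_attract(octamers, pwms: dict, top_fraction: float = 0.05, min_score: float = 0.9) -> pd.DataFrame:
    """Score octamers against PWMs; keep per-PWM the top ``top_fraction``
    by score and then drop scores below ``min_score``."""
    rows = []
    for pwm_id, pwm in pwms.items():
        scores = [(o, rpm_score(o, pwm)) for o in octamers]
        scores.sort(key=lambda t: -t[1])
        n_keep = max(1, int(math.ceil(top_fraction * len(scores))))
        for o, s in scores[:n_keep]:
            if s >= min_score:
                rows.append({"octamer": o, "pwm_id": pwm_id, "rpm_score": s})
    return pd.DataFrame(rows, columns=["octamer", "pwm_id", "rpm_score"])
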