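"""Two-state explicit-duration hidden semi-Markov segmentation.

The generative model: a chromosome alternates between two hidden states
(PAD / non-PAD). Each visit to state ``s`` lasts a *sojourn* of ``u``
fragment ends, ``u`` drawn from a gamma density (shape alpha_s, scale
theta_s) discretized to unit intervals and truncated at ``M``. While in
state ``s`` every fragment end independently emits one of 5 read-count
categories — [0], [1], [2-4], [5-7], [>7] reads — from a multinomial row
``B[s]``. With two states and no self-transitions the transition matrix is
the fixed alternation [[0,1],[1,0]]; the free parameters are the emission
rows, the gamma sojourns, and the initial-state probabilities.

Fitting is by EM: the E-step runs the explicit-duration forward-backward
recursions (in log space) to obtain per-position state occupancies and
expected sojourn-length counts; the M-step re-estimates emission rows and
initial probabilities in closed form and the gamma parameters by method of
moments on the expected sojourn mean and variance. Decoding is
explicit-duration Viterbi (guaranteeing contiguous segments) or smoothed
posterior argmax.

:class:`HSMMSegmenter` follows the scikit-learn estimator protocol:
``fit(X)`` on a list of category sequences, ``predict`` / ``predict_proba``
per sequence, fitted attributes with trailing underscores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .io import CountTrack, FragmentEndMap

__all__ = [
    "N_CATEGORIES",
    "CATEGORY_BOUNDS",
    "CategorySequence",
    "StateCalls",
    "FitResult",
    "HSMMSegmenter",
    "bin_counts",
    "discretize_sojourn",
    "em_fit",
    "decode",
]

N_CATEGORIES = 5
# np.digitize boundaries: 0 -> cat0, 1 -> cat1, 2-4 -> cat2, 5-7 -> cat3, >=8 -> cat4
CATEGORY_BOUNDS = np.array([1, 2, 5, 8])

_NEG_INF = -np.inf
# finite stand-in for log(0): keeps the prefix-sum trick for segment emission
# products free of inf-inf = nan while making impossible paths lose every
# comparison; any total below _IMPOSSIBLE is treated as zero probability.
_LOG_ZERO = -1e15
_IMPOSSIBLE = -1e13


class DecodingError(ValueError):
    """The sequence has zero probability under the model."""


@dataclass
class CategorySequence:
    """Read-count categories per fragment end, one array per chromosome."""

    fragends: FragmentEndMap
    codes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.codes.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.size != self.fragends.n_ends(chrom):
                raise ValueError(f"{chrom}: code length does not match the map")
            if arr.size and (arr.min() < 0 or arr.max() >= N_CATEGORIES):
                raise ValueError(f"{chrom}: category outside 0..{N_CATEGORIES - 1}")
            self.codes[chrom] = arr

    def sequences(self) -> list[np.ndarray]:
        return [self.codes[c] for c in self.fragends.chromosomes]

    def concat(self) -> np.ndarray:
        return np.concatenate(self.sequences()) if self.codes else np.empty(0, np.int64)


@dataclass
class StateCalls:
    """PAD / non-PAD label per fragment end (True = PAD)."""

    fragends: FragmentEndMap
    is_pad: np.ndarray  # bool, genome-wide concatenation in karyotype order
    posterior_pad: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.is_pad = np.asarray(self.is_pad, dtype=bool)
        if self.is_pad.size != self.fragends.n_ends():
            raise ValueError("calls length does not match the fragment-end map")

    def per_chrom(self) -> dict[str, np.ndarray]:
        out, pos = {}, 0
        for chrom in self.fragends.chromosomes:
            n = self.fragends.n_ends(chrom)
            out[chrom] = self.is_pad[pos : pos + n]
            pos += n
        return out


@dataclass
class FitResult:
    model: "HSMMSegmenter"
    loglik_trace: list[float]
    converged: bool
    seed: int | None = None


def bin_counts(track: CountTrack) -> CategorySequence:
    """Bin integer read counts into the 5 emission categories.

    0 reads -> 0, 1 read -> 1, 2-4 reads -> 2, 5-7 reads -> 3, >7 reads -> 4.
    """
    vals = track.values
    if np.any(vals < 0):
        raise ValueError("negative counts cannot be binned")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be integers; bin raw (not normalized) counts")
    ivals = np.round(vals).astype(np.int64)
    codes = np.digitize(ivals, CATEGORY_BOUNDS)
    seq, pos = {}, 0
    for chrom in track.fragends.chromosomes:
        n = track.fragends.n_ends(chrom)
        seq[chrom] = codes[pos : pos + n]
        pos += n
    return CategorySequence(track.fragends, seq)


def discretize_sojourn(shape: float, scale: float, max_duration: int) -> np.ndarray:
    """Discretized, truncated gamma sojourn pmf over durations 1..max_duration.

    pmf(u) is proportional to CDF(u) - CDF(u-1), renormalized to sum to 1.
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma shape and scale must be positive")
    if max_duration < 1:
        raise ValueError("max_duration must be >= 1")
    u = np.arange(max_duration + 1)
    cdf = stats.gamma.cdf(u, a=shape, scale=scale)
    pmf = np.diff(cdf)
    total = pmf.sum()
    if total <= 0:
        # all mass beyond the truncation point; put it at max_duration
        pmf = np.zeros(max_duration)
        pmf[-1] = 1.0
        return pmf
    return pmf / total


def _safe_log(x: np.ndarray) -> np.ndarray:
    """log with zeros mapped to the finite _LOG_ZERO sentinel."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, _LOG_ZERO)
    pos = x > 0
    out[pos] = np.log(x[pos])
    return out


def _logsumexp(v: np.ndarray) -> float:
    m = v.max()
    if m == _NEG_INF:
        return _NEG_INF
    return float(m + np.log(np.exp(v - m).sum()))


def _emission_cumsums(codes: np.ndarray, logB: np.ndarray) -> np.ndarray:
    """cum[s, t] = sum of log-emissions of state s over positions < t."""
    lb = logB[:, codes]  # (2, T)
    cum = np.zeros((2, codes.size + 1))
    np.cumsum(lb, axis=1, out=cum[:, 1:])
    return cum


def _forward(cum: np.ndarray, ld: np.ndarray, lpi: np.ndarray) -> tuple[np.ndarray, float]:
    T = cum.shape[1] - 1
    M = ld.shape[1]
    la = np.full((2, T), _NEG_INF)
    for t in range(T):
        U = min(t + 1, M)
        u = np.arange(1, U + 1)
        a = t - u + 1  # decreasing segment starts
        for s in (0, 1):
            prev = la[1 - s, a - 1].copy()
            if a[-1] == 0:
                prev[-1] = lpi[s]
            la[s, t] = _logsumexp(ld[s, :U] + (cum[s, t + 1] - cum[s, a]) + prev)
    return la, _logsumexp(la[:, T - 1])


def _backward(cum: np.ndarray, ld: np.ndarray) -> np.ndarray:
    T = cum.shape[1] - 1
    M = ld.shape[1]
    lbw = np.full((2, T), _NEG_INF)
    lbw[:, T - 1] = 0.0
    for t in range(T - 2, -1, -1):
        for s in (0, 1):
            ns = 1 - s
            U = min(M, T - 1 - t)
            u = np.arange(1, U + 1)
            lbw[s, t] = _logsumexp(
                ld[ns, :U] + (cum[ns, t + 1 + u] - cum[ns, t + 1]) + lbw[ns, t + u]
            )
    return lbw


def _expected_counts(
    codes: np.ndarray,
    cum: np.ndarray,
    ld: np.ndarray,
    lpi: np.ndarray,
    la: np.ndarray,
    lbw: np.ndarray,
    loglik: float,
):
    """E-step sufficient statistics for one sequence.

    Returns (occupancy (2,T), duration counts eta (2,M), segment-start
    probabilities sigma (2,T)).
    """
    T = codes.size
    M = ld.shape[1]
    eta = np.zeros((2, M))
    sigma = np.zeros((2, T))
    for a in range(T):
        U = min(M, T - a)
        u = np.arange(1, U + 1)
        for s in (0, 1):
            startw = lpi[s] if a == 0 else la[1 - s, a - 1]
            if startw < _IMPOSSIBLE:
                continue
            logw = (
                startw
                + ld[s, :U]
                + (cum[s, a + u] - cum[s, a])
                + lbw[s, a + u - 1]
                - loglik
            )
            w = np.exp(logw)
            eta[s, :U] += w
            sigma[s, a] = w.sum()
    ends = np.exp(la + lbw - loglik)
    occ = np.zeros((2, T))
    occ[:, T - 1] = ends[:, T - 1]
    for t in range(T - 2, -1, -1):
        occ[:, t] = occ[:, t + 1] + ends[:, t] - sigma[:, t + 1]
    occ = np.clip(occ, 0.0, 1.0)
    return occ, eta, sigma


def _viterbi(
    codes: np.ndarray, logB: np.ndarray, ld: np.ndarray, lpi: np.ndarray
) -> np.ndarray:
    """MAP segmentation. Ties break toward the lower-indexed state and, via
    first-argmax over durations, toward shorter segments."""
    T = codes.size
    M = ld.shape[1]
    cum = _emission_cumsums(codes, logB)
    lv = np.full((2, T), _NEG_INF)
    bp = np.zeros((2, T), dtype=np.int64)
    for t in range(T):
        U = min(t + 1, M)
        u = np.arange(1, U + 1)
        a = t - u + 1
        for s in (0, 1):
            prev = lv[1 - s, a - 1].copy()
            if a[-1] == 0:
                prev[-1] = lpi[s]
            val = ld[s, :U] + (cum[s, t + 1] - cum[s, a]) + prev
            k = int(np.argmax(val))  # first max -> smallest duration
            lv[s, t] = val[k]
            bp[s, t] = k + 1
    if max(lv[0, T - 1], lv[1, T - 1]) < _IMPOSSIBLE:
        raise DecodingError(
            "sequence has zero probability under the model; "
            "consider a larger emission floor"
        )
    s = 0 if lv[0, T - 1] >= lv[1, T - 1] else 1
    path = np.empty(T, dtype=np.int64)
    t = T - 1
    while t >= 0:
        u = int(bp[s, t])
        path[t - u + 1 : t + 1] = s
        t -= u
        s = 1 - s
    return path


class HSMMSegmenter(BaseEstimator):
    """Two-state explicit-duration HSMM over 5 read-count categories.

    Parameters
    ----------
    tol : float
        EM stops when the relative log-likelihood improvement drops below
        this value.
    max_iter : int
        Maximum EM iterations.
    emission_floor : float
        Lower bound applied to emission probabilities after each M-step
        (rows renormalized), preventing zero-probability lockout.
    duration_mass : float
        The gamma sojourn pmf is truncated at the smallest duration whose
        CDF reaches this mass (recomputed as parameters move, never
        decreased across iterations).
    max_duration_cap : int
        Hard upper bound on the truncation length, in fragment ends.
    init_window : int
        Window (fragment ends) of the running-mean threshold used to seed
        the two states deterministically.
    random_state : int or None
        Recorded for provenance; initialization is deterministic.

    Attributes
    ----------
    emission_ : (2, 5) array — fitted multinomial rows.
    sojourn_shape_, sojourn_scale_ : (2,) arrays — fitted gamma parameters.
    startprob_ : (2,) array — initial-state probabilities.
    max_duration_ : int — truncation length of the sojourn pmf.
    duration_pmf_ : (2, max_duration_) array.
    pad_state_ : int — the state with the greater expected emitted
        category, labeled PAD by convention.
    loglik_trace_ : list of per-iteration log-likelihoods (non-decreasing).
    converged_ : bool; n_iter_ : int.
    identifiable_ : False when the two emission rows collapsed onto each
        other (degenerate input).
    """

    def __init__(
        self,
        tol: float = 1e-6,
        max_iter: int = 200,
        emission_floor: float = 1e-6,
        duration_mass: float = 0.999,
        max_duration_cap: int = 5000,
        init_window: int = 11,
        random_state: int | None = 0,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.emission_floor = emission_floor
        self.duration_mass = duration_mass
        self.max_duration_cap = max_duration_cap
        self.init_window = init_window
        self.random_state = random_state

    # ------------------------------------------------------------------
    @staticmethod
    def _as_sequences(X) -> list[np.ndarray]:
        if isinstance(X, CategorySequence):
            seqs = X.sequences()
        elif isinstance(X, np.ndarray) and X.ndim == 1:
            seqs = [X]
        else:
            seqs = [np.asarray(x, dtype=np.int64) for x in X]
        seqs = [s for s in seqs if s.size > 0]
        if not seqs:
            raise ValueError("no non-empty sequences")
        for s in seqs:
            if s.size < 2:
                raise ValueError("each sequence must have length >= 2")
            if s.min() < 0 or s.max() >= N_CATEGORIES:
                raise ValueError("category codes must be in 0..4")
        return seqs

    def _initial_parameters(self, seqs: list[np.ndarray]):
        """Deterministic seeding: threshold a running-mean of category codes
        at its median; high side seeds state 1, low side state 0; gamma
        sojourns from the run lengths of that thresholding."""
        half = max(1, self.init_window // 2)
        counts = np.full((2, N_CATEGORIES), 1.0)  # Laplace smoothing
        run_lengths: dict[int, list[int]] = {0: [], 1: []}
        first = np.zeros(2)
        for seq in seqs:
            csum = np.concatenate([[0.0], np.cumsum(seq)])
            idx = np.arange(seq.size)
            lo = np.maximum(idx - half, 0)
            hi = np.minimum(idx + half + 1, seq.size)
            smooth = (csum[hi] - csum[lo]) / (hi - lo)
            thr = np.median(smooth)
            lab = (smooth > thr).astype(np.int64)
            if lab.min() == lab.max():  # flat sequence: split in half
                lab[: seq.size // 2] = 0
                lab[seq.size // 2 :] = 1
            for s in (0, 1):
                np.add.at(counts[s], seq[lab == s], 1.0)
            first[lab[0]] += 1.0
            boundaries = np.flatnonzero(np.diff(lab)) + 1
            starts = np.concatenate([[0], boundaries])
            stops = np.concatenate([boundaries, [seq.size]])
            for st, sp in zip(starts, stops):
                run_lengths[int(lab[st])].append(sp - st)
        B = counts / counts.sum(axis=1, keepdims=True)
        pi = (first + 1.0) / (first + 1.0).sum()
        shape = np.empty(2)
        scale = np.empty(2)
        for s in (0, 1):
            runs = np.asarray(run_lengths[s], dtype=float)
            m = runs.mean() if runs.size else 10.0
            v = runs.var() if runs.size > 1 else m
            v = max(v, 1e-2)
            shape[s] = np.clip(m * m / v, 1e-2, 1e4)
            scale[s] = max(v / m, 1e-6)
        return B, pi, shape, scale

    def _truncation(self, shape, scale, prev_m: int, max_len: int) -> int:
        m = 1
        for s in (0, 1):
            m = max(m, int(np.ceil(stats.gamma.ppf(self.duration_mass, a=shape[s],
                                                   scale=scale[s]))))
        m = max(m, prev_m)  # never shrink: keeps the LL trace comparable
        return int(min(m, self.max_duration_cap, max_len))

    def fit(self, X, y=None) -> "HSMMSegmenter":
        seqs = self._as_sequences(X)
        max_len = max(s.size for s in seqs)
        B, pi, shape, scale = self._initial_parameters(seqs)
        M = self._truncation(shape, scale, 1, max_len)
        ld = np.log(np.vstack([discretize_sojourn(shape[s], scale[s], M) + 1e-300
                               for s in (0, 1)]))
        trace: list[float] = []
        converged = False
        snapshot = (B, pi, shape, scale, M, ld)
        for _ in range(self.max_iter):
            logB = _safe_log(B)
            lpi = _safe_log(pi)
            tot_ll = 0.0
            em_counts = np.zeros((2, N_CATEGORIES))
            eta_tot = np.zeros((2, M))
            pi_counts = np.zeros(2)
            for seq in seqs:
                cum = _emission_cumsums(seq, logB)
                la, ll = _forward(cum, ld, lpi)
                if not np.isfinite(ll) or ll < _IMPOSSIBLE:
                    raise DecodingError(
                        "zero-probability sequence during EM; "
                        "consider a larger emission floor"
                    )
                lbw = _backward(cum, ld)
                occ, eta, sigma = _expected_counts(seq, cum, ld, lpi, la, lbw, ll)
                tot_ll += ll
                for c in range(N_CATEGORIES):
                    mask = seq == c
                    em_counts[:, c] += occ[:, mask].sum(axis=1)
                eta_tot += eta
                pi_counts += sigma[:, 0]
            if trace and tot_ll < trace[-1]:
                # a regression can only come from sub-tol numerical noise
                # (emission floor renormalization); restore the previous
                # iterate so the recorded trace stays non-decreasing
                B, pi, shape, scale, M, ld = snapshot
                converged = True
                break
            trace.append(tot_ll)
            if len(trace) > 1:
                prev = trace[-2]
                if tot_ll - prev < self.tol * abs(prev):
                    converged = True
                    break
            snapshot = (B, pi, shape, scale, M, ld)
            # ---- M-step ----
            pi = pi_counts / pi_counts.sum()
            pi = np.clip(pi, 1e-12, None)
            pi = pi / pi.sum()
            B = em_counts / em_counts.sum(axis=1, keepdims=True)
            B = np.maximum(B, self.emission_floor)
            B = B / B.sum(axis=1, keepdims=True)
            shape, scale = self._update_sojourn(eta_tot, ld, shape, scale)
            M = self._truncation(shape, scale, M, max_len)
            ld = np.log(np.vstack([discretize_sojourn(shape[s], scale[s], M) + 1e-300
                                   for s in (0, 1)]))

        self.emission_ = B
        self.startprob_ = pi
        self.sojourn_shape_ = shape
        self.sojourn_scale_ = scale
        self.max_duration_ = M
        self.duration_pmf_ = np.exp(ld)
        self.loglik_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = len(trace)
        expected_cat = (B * np.arange(N_CATEGORIES)).sum(axis=1)
        self.pad_state_ = int(np.argmax(expected_cat))
        self.identifiable_ = bool(np.abs(B[0] - B[1]).max() > 1e-3)
        return self

    def _update_sojourn(self, eta: np.ndarray, ld: np.ndarray, shape, scale):
        """Gamma sojourn update from expected duration counts.

        Method of moments on the expected duration mean and variance is the
        primary (closed-form) estimator. Because MoM matches moments rather
        than likelihood, it can occasionally score worse than the previous
        parameters on the expected duration log-likelihood
        sum_u eta[s,u] log d_s(u); in that case the update is refined by a
        direct numerical maximization of that objective (started from the
        MoM point), and the previous parameters are kept only if even the
        refinement fails to improve. This preserves EM monotonicity.
        """
        from scipy.optimize import minimize

        M = eta.shape[1]
        u = np.arange(1, M + 1)
        new_shape = shape.copy()
        new_scale = scale.copy()
        for s in (0, 1):
            W = eta[s].sum()
            if W <= 0:
                continue
            m = float((u * eta[s]).sum() / W)
            v = float((u * u * eta[s]).sum() / W - m * m)
            v = max(v, 1e-2)
            cand_shape = float(np.clip(m * m / v, 1e-2, 1e4))
            cand_scale = max(v / m, 1e-6)
            q_old = float((eta[s] * ld[s]).sum())

            def q_of(sh: float, sc: float) -> float:
                d = np.log(discretize_sojourn(sh, sc, M) + 1e-300)
                return float((eta[s] * d).sum())

            q_mom = q_of(cand_shape, cand_scale)
            if q_mom < q_old:
                res = minimize(
                    lambda p: -q_of(float(np.exp(p[0])), float(np.exp(p[1]))),
                    x0=np.log([cand_shape, cand_scale]),
                    method="Nelder-Mead",
                    options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-8},
                )
                opt_shape, opt_scale = np.exp(res.x)
                if -res.fun > max(q_mom, q_old):
                    cand_shape = float(np.clip(opt_shape, 1e-2, 1e4))
                    cand_scale = float(max(opt_scale, 1e-6))
                    q_mom = q_of(cand_shape, cand_scale)
            if q_mom >= q_old:
                new_shape[s] = cand_shape
                new_scale[s] = cand_scale
        return new_shape, new_scale

    # ------------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "emission_"):
            raise ValueError("HSMMSegmenter is not fitted")

    def _log_params(self):
        return (
            _safe_log(self.emission_),
            _safe_log(self.duration_pmf_),
            _safe_log(self.startprob_),
        )

    def predict(self, x, method: str = "viterbi") -> np.ndarray:
        """State index (0/1) per position of one sequence."""
        self._check_fitted()
        x = np.asarray(x, dtype=np.int64)
        logB, ld, lpi = self._log_params()
        if method == "viterbi":
            return _viterbi(x, logB, ld, lpi)
        if method == "posterior":
            return np.argmax(self.predict_proba(x), axis=1)
        raise ValueError(f"unknown decoding method {method!r}")

    def predict_proba(self, x) -> np.ndarray:
        """Smoothed per-position state posteriors, shape (T, 2)."""
        self._check_fitted()
        x = np.asarray(x, dtype=np.int64)
        logB, ld, lpi = self._log_params()
        cum = _emission_cumsums(x, logB)
        la, ll = _forward(cum, ld, lpi)
        if not np.isfinite(ll) or ll < _IMPOSSIBLE:
            raise DecodingError(
                "sequence has zero probability under the model; "
                "consider a larger emission floor"
            )
        lbw = _backward(cum, ld)
        occ, _, _ = _expected_counts(x, cum, ld, lpi, la, lbw, ll)
        return occ.T

    def score(self, X, y=None) -> float:
        """Total log-likelihood of the sequences under the fitted model."""
        self._check_fitted()
        seqs = self._as_sequences(X)
        logB, ld, lpi = self._log_params()
        total = 0.0
        for seq in seqs:
            cum = _emission_cumsums(seq, logB)
            _, ll = _forward(cum, ld, lpi)
            total += ll
        return total

    def set_model(self, emission, sojourn_shape, sojourn_scale, startprob,
                  max_duration: int) -> "HSMMSegmenter":
        """Install explicit parameters (bypassing fit), e.g. ground truth."""
        self.emission_ = np.asarray(emission, dtype=float)
        self.sojourn_shape_ = np.asarray(sojourn_shape, dtype=float)
        self.sojourn_scale_ = np.asarray(sojourn_scale, dtype=float)
        self.startprob_ = np.asarray(startprob, dtype=float)
        self.max_duration_ = int(max_duration)
        self.duration_pmf_ = np.vstack([
            discretize_sojourn(self.sojourn_shape_[s], self.sojourn_scale_[s],
                               self.max_duration_)
            for s in (0, 1)
        ])
        self.loglik_trace_ = []
        self.converged_ = True
        self.n_iter_ = 0
        expected_cat = (self.emission_ * np.arange(N_CATEGORIES)).sum(axis=1)
        self.pad_state_ = int(np.argmax(expected_cat))
        self.identifiable_ = bool(np.abs(self.emission_[0] - self.emission_[1]).max() > 1e-3)
        return self

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "emission": self.emission_.tolist(),
            "sojourn_shape": self.sojourn_shape_.tolist(),
            "sojourn_scale": self.sojourn_scale_.tolist(),
            "startprob": self.startprob_.tolist(),
            "max_duration": int(self.max_duration_),
            "pad_state": int(self.pad_state_),
            "random_state": self.random_state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HSMMSegmenter":
        est = cls(random_state=d.get("random_state"))
        est.set_model(d["emission"], d["sojourn_shape"], d["sojourn_scale"],
                      d["startprob"], d["max_duration"])
        return est


def em_fit(
    sequences,
    init: HSMMSegmenter | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int | None = 0,
) -> FitResult:
    """Fit the two-state HSMM to one replicate's category sequences."""
    est = init if init is not None else HSMMSegmenter(
        tol=tol, max_iter=max_iter, random_state=seed
    )
    est.set_params(tol=tol, max_iter=max_iter)
    est.fit(sequences)
    return FitResult(est, est.loglik_trace_, est.converged_, seed)


def decode(
    model: HSMMSegmenter,
    sequence: CategorySequence,
    method: str = "viterbi",
    with_posterior: bool = False,
) -> StateCalls:
    """Label every fragment end PAD / non-PAD for a whole CategorySequence."""
    pad = model.pad_state_
    labels = []
    posts = [] if with_posterior else None
    for seq in sequence.sequences():
        states = model.predict(seq, method=method)
        labels.append(states == pad)
        if with_posterior:
            posts.append(model.predict_proba(seq)[:, pad])
    return StateCalls(
        sequence.fragends,
        np.concatenate(labels),
        np.concatenate(posts) if with_posterior else None,
    )
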