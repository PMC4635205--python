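"""Information-theoretic behavior-contagion measures between two individuals.

The mutual exchange of behavior between two interacting individuals is
modeled as a noisy channel: one individual's behavioral symbols F are the
inputs, the other's observed symbols G the outputs. The "contagion" of an
event with probability p is its surprisal I(p) = log(1/p); the expected
contagion of a symbol distribution is its entropy; the reduction in
uncertainty about F from observing G is the mutual contagion I(F;G); and
the strongest possible coupling of the dyad is the channel capacity
C = max_{P(f)} I(F;G).

All quantities are computed in natural log internally and converted to the
requested unit (bits / trits / nats / Hartleys) at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize
from scipy.special import entr, logsumexp, rel_entr, xlogy

__all__ = [
    "UNIT_NAMES",
    "contagion",
    "entropy",
    "entropy_continuous",
    "expected_contagion",
    "kraft_check",
    "source_coding_bound",
    "JointDistribution",
    "MutualContagion",
    "mutual_contagion",
    "channel_capacity",
    "reverse_channel_to_forward",
    "MaxEntResult",
    "maxent_distribution",
    "InfeasibleConstraints",
]

#: Named logarithm bases and the units they induce.
UNIT_NAMES = {2: "bits", 3: "trits", math.e: "nats", 10: "Hartleys"}

_NORM_TOL = 1e-9


def _log_scale(base: float) -> float:
    if base <= 0 or base == 1:
        raise ValueError("log base must be positive and != 1")
    return math.log(base)


def _validate_dist(p, name: str = "distribution") -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if np.any(arr < -1e-15):
        raise ValueError(f"{name} has negative mass")
    if abs(arr.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"{name} must sum to 1 (got {arr.sum():.12g})")
    return np.clip(arr, 0.0, None)


def contagion(p: float, base: float = 2) -> float:
    """Contagion (surprisal) of an event: I(p) = log_base(1/p).

    I(1) = 0 (a sure event carries no behavior); I is additive over
    independent events. p = 0 returns +inf.
    """
    if p < 0 or p > 1:
        raise ValueError("p must be in [0, 1]")
    scale = _log_scale(base)
    if p == 0:
        return math.inf
    if p == 1:
        return 0.0
    return -math.log(p) / scale


def entropy(dist, base: float = 2) -> float:
    """Entropy S(P) = sum_i p_i log(1/p_i), with 0*log(1/0) := 0."""
    p = _validate_dist(dist)
    return float(entr(p).sum() / _log_scale(base))


def entropy_continuous(density: Sequence[float], x: Sequence[float], base: float = 2) -> float:
    """Differential entropy from density values evaluated on a grid.

    Trapezoid integration of p(x) log(1/p(x)); the caller supplies the grid
    and the density evaluations.
    """
    f = np.asarray(density, dtype=float)
    grid = np.asarray(x, dtype=float)
    if f.shape != grid.shape or f.ndim != 1:
        raise ValueError("density and x must be 1-D arrays of equal length")
    if np.any(f < 0):
        raise ValueError("density must be non-negative")
    integrand = entr(f)
    return float(np.trapezoid(integrand, grid) / _log_scale(base))


def expected_contagion(dist, values, base: float = 2) -> float:
    """Weighted mean E[H] = sum_i h_i p_i of per-symbol contagion values.

    When h_i = I(p_i) (in the same unit), this equals the entropy of the
    distribution.
    """
    p = _validate_dist(dist)
    h = np.asarray(values, dtype=float)
    if h.shape != p.shape:
        raise ValueError("values must align with the distribution")
    # The unit of the result is the unit of the supplied values; ``base`` is
    # accepted for interface symmetry but does not rescale user values.
    _log_scale(base)
    return float(np.sum(np.where(p > 0, h * p, 0.0)))


def kraft_check(lengths: Sequence[int], code_base: int = 2) -> tuple[float, bool]:
    """Kraft–McMillan sum K = sum_i base^(-l_i) and feasibility flag (K <= 1)."""
    if len(lengths) == 0:
        raise ValueError("code must have at least one length")
    if code_base < 2 or int(code_base) != code_base:
        raise ValueError("code_base must be an integer >= 2")
    l = np.asarray(lengths, dtype=float)
    if np.any(l < 1) or np.any(l != np.round(l)):
        raise ValueError("lengths must be positive integers")
    k = float(np.sum(float(code_base) ** (-l)))
    return k, k <= 1.0 + 1e-12


def source_coding_bound(
    dist, lengths: Sequence[int], code_base: int = 2, base: float = 2
) -> tuple[float, float, bool]:
    """Source-coding inequality S(B) <= L log(beta) with L = sum p_i l_i.

    Returns (entropy, L*log_base(beta), satisfied). The entropy of the
    source lower-bounds the expected code length of any uniquely decodable
    code over a beta-ary alphabet.
    """
    p = _validate_dist(dist)
    l = np.asarray(lengths, dtype=float)
    if l.shape != p.shape:
        raise ValueError("lengths must align with the distribution")
    s = entropy(p, base=base)
    avg_len = float(np.sum(p * l)) * math.log(code_base) / _log_scale(base)
    return s, avg_len, s <= avg_len + 1e-12


class JointDistribution:
    """Joint distribution P(f_i, g_j) over finite input/output alphabets."""

    def __init__(self, matrix) -> None:
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("joint distribution must be a 2-D matrix")
        if np.any(m < -1e-15):
            raise ValueError("joint distribution has negative mass")
        if abs(m.sum() - 1.0) > _NORM_TOL:
            raise ValueError("joint distribution must sum to 1")
        self.matrix = np.clip(m, 0.0, None)

    @property
    def p_f(self) -> np.ndarray:
        """Input marginal P(f_i)."""
        return self.matrix.sum(axis=1)

    @property
    def p_g(self) -> np.ndarray:
        """Output marginal P(g_j)."""
        return self.matrix.sum(axis=0)

    @classmethod
    def from_channel(cls, channel, input_dist) -> "JointDistribution":
        """Build P(f, g) = P(f) P(g|f) from a forward channel matrix."""
        ch = np.asarray(channel, dtype=float)
        p = _validate_dist(input_dist, "input distribution")
        if ch.shape[0] != p.size:
            raise ValueError("channel rows must match the input alphabet")
        for i, row in enumerate(ch):
            _validate_dist(row, f"channel row {i}")
        return cls(p[:, None] * ch)


@dataclass(frozen=True)
class MutualContagion:
    mutual: float  # I(F;G)
    h_f: float  # S(F)
    h_g: float  # S(G)
    h_f_given_g: float  # S(F|G)
    h_g_given_f: float  # S(G|F)
    h_joint: float  # S(F,G)
    unit: str


def mutual_contagion(joint: Union[JointDistribution, np.ndarray], base: float = 2) -> MutualContagion:
    """All entropic quantities of a dyad by direct summation.

    Identities S(F,G) = S(F) + S(G|F) = S(G) + S(F|G) and
    I(F;G) = S(F) - S(F|G) hold to numerical precision; I = 0 iff the joint
    factorizes.
    """
    if not isinstance(joint, JointDistribution):
        joint = JointDistribution(joint)
    m = joint.matrix
    scale = _log_scale(base)
    pf, pg = joint.p_f, joint.p_g
    h_f = float(entr(pf).sum() / scale)
    h_g = float(entr(pg).sum() / scale)
    h_joint = float(entr(m).sum() / scale)
    # I(F;G) = KL( P(F,G) || P(F)P(G) ), computed with the 0 log 0 convention.
    mutual = float(rel_entr(m, np.outer(pf, pg)).sum() / scale)
    return MutualContagion(
        mutual=mutual,
        h_f=h_f,
        h_g=h_g,
        h_f_given_g=h_joint - h_g,
        h_g_given_f=h_joint - h_f,
        h_joint=h_joint,
        unit=UNIT_NAMES.get(base, f"log{base} units"),
    )


def reverse_channel_to_forward(p_f_given_g, p_g) -> tuple[np.ndarray, np.ndarray]:
    """Convert a backward characterization {P(f_i|g_j)} plus P(g) to the
    forward orientation (P(g|f) rows, input marginal P(f)).

    The source characterizes the dyadic channel by the set {P(f_i | g_j)};
    capacity is conventionally maximized over input distributions, so both
    orientations are exposed explicitly.
    """
    back = np.asarray(p_f_given_g, dtype=float)  # shape (n_f, n_g), columns sum to 1
    pg = _validate_dist(p_g, "output distribution")
    if back.shape[1] != pg.size:
        raise ValueError("columns of P(f|g) must match the output alphabet")
    for j in range(back.shape[1]):
        _validate_dist(back[:, j], f"P(f|g_{j})")
    joint = back * pg[None, :]
    pf = joint.sum(axis=1)
    if np.any(pf == 0):
        raise ValueError("input marginal has zero-mass symbols; drop them first")
    forward = joint / pf[:, None]
    return forward, pf


def channel_capacity(
    channel, base: float = 2, tol: float = 1e-12, max_iter: int = 100_000
) -> tuple[float, np.ndarray]:
    """Channel capacity C = max over input distributions of I(F;G).

    Alternating maximization (Blahut–Arimoto): the iteration is monotone
    non-decreasing in capacity and stops when the bound gap falls below
    ``tol``. Returns (capacity, maximizing input distribution).
    """
    ch = np.asarray(channel, dtype=float)
    if ch.ndim != 2:
        raise ValueError("channel must be a 2-D matrix of rows P(g|f)")
    for i, row in enumerate(ch):
        _validate_dist(row, f"channel row {i}")
    n = ch.shape[0]
    p = np.full(n, 1.0 / n)
    scale = _log_scale(base)
    # Per-row negative conditional entropy sum_j P(g|f) ln P(g|f).
    row_neg_ent = -entr(ch).sum(axis=1)
    with np.errstate(divide="ignore"):
        log_ch = np.where(ch > 0, np.log(ch), 0.0)
    for _ in range(max_iter):
        q = p @ ch  # output distribution
        with np.errstate(divide="ignore"):
            log_q = np.where(q > 0, np.log(q), 0.0)
        # D(f) = KL(P(.|f) || q) in nats
        d = row_neg_ent - ch @ log_q
        # Capacity bounds: sum_f p(f) D(f) <= C <= max_f D(f)
        lower = float(p @ d)
        upper = float(d.max())
        if upper - lower < tol * max(1.0, upper):
            break
        w = p * np.exp(d - d.max())
        p = w / w.sum()
    q = p @ ch
    cap = float(rel_entr(p[:, None] * ch, np.outer(p, q)).sum() / scale)
    return max(cap, 0.0), p


class InfeasibleConstraints(ValueError):
    """Raised when maximum-entropy constraint targets are unattainable."""


@dataclass(frozen=True)
class MaxEntResult:
    dist: np.ndarray
    multipliers: np.ndarray  # lambda_r, one per constraint
    log_partition: float  # lambda = ln H, the normalization multiplier
    residuals: np.ndarray


def maxent_distribution(
    constraint_values, targets, tol: float = 1e-10, n_symbols: Optional[int] = None
) -> MaxEntResult:
    """Maximum-entropy distribution under linear macroscopic constraints.

    Maximizes sum_i f_i log(1/f_i) subject to f_i >= 0, sum f_i = 1 and
    sum_i f_i s_i^(r) = s_r for each constraint r. The solution has the
    exponential-family form f_i = exp(-lambda - sum_r lambda_r s_i^(r)) with
    e^lambda = H(lambda_1..lambda_K), the partition sum. Multipliers are
    found by minimizing the convex dual ln H + sum_r lambda_r s_r.

    ``constraint_values`` is a (K, n) array (one row of per-symbol values
    s_i^(r) per constraint); with K = 0 pass ``n_symbols`` and the uniform
    distribution is returned.
    """
    s = np.asarray(constraint_values, dtype=float)
    t = np.atleast_1d(np.asarray(targets, dtype=float))
    if s.size == 0:
        if n_symbols is None:
            raise ValueError("n_symbols required when there are no constraints")
        f = np.full(n_symbols, 1.0 / n_symbols)
        return MaxEntResult(f, np.zeros(0), math.log(n_symbols), np.zeros(0))
    if s.ndim == 1:
        s = s[None, :]
    if t.shape != (s.shape[0],):
        raise ValueError("one target per constraint row required")
    # Necessary feasibility: each target inside the hull of its own values.
    if np.any(t < s.min(axis=1) - 1e-12) or np.any(t > s.max(axis=1) + 1e-12):
        raise InfeasibleConstraints("targets outside the convex hull of constraint values")

    def dual(lam):
        expo = -(lam @ s)
        return logsumexp(expo) + lam @ t

    def grad(lam):
        expo = -(lam @ s)
        w = np.exp(expo - logsumexp(expo))
        return t - s @ w

    res = minimize(dual, np.zeros(s.shape[0]), jac=grad, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 5000})
    lam = res.x
    expo = -(lam @ s)
    log_h = float(logsumexp(expo))
    f = np.exp(expo - log_h)
    residuals = s @ f - t
    if np.any(np.abs(residuals) > max(tol, 1e3 * tol * np.max(np.abs(t) + 1.0))):
        raise InfeasibleConstraints(
            f"constraint residuals {residuals} exceed tolerance; targets may be "
            "on or outside the boundary of the feasible set"
        )
    return MaxEntResult(dist=f, multipliers=lam, log_partition=log_h, residuals=residuals)
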