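"""Fisher information, D-objective and D-efficiency for sampling schedules.

Measurements of one subject at times t1..tn are modelled as multivariate
normal around the kinetics mean with a known, constant covariance: common
variance sigma^2 and AR(1) correlation rho^|i-j| between the i-th and j-th
measurement *in measurement order*.  Because the correlation is index-based,
the covariance does not depend on the sampling times themselves, which makes
the optimal times invariant to the choice of sigma and rho.

With mean gradient matrix J (n rows, one per time; p columns, one per curve
parameter) the Fisher information is FIM = J' Sigma^-1 J.  D-optimal
schedules minimize -ln(det(FIM) + 1); the added constant maps every
degenerate schedule (det = 0) to objective 0 and keeps the objective stable
when det(FIM) is tiny.  Designs are compared by D-efficiency,
(det FIM(candidate) / det FIM(reference))^(1/p), both evaluated under the
same (true) parameters.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, digamma

from .types import CurveParameters, Design, ErrorModel

__all__ = [
    "ar1_covariance",
    "mean_gradient",
    "fisher_information",
    "d_objective",
    "d_efficiency",
    "FastDObjective",
]

#: times are clipped to at least this (days) when c = 0 to avoid log(0)
_TIME_FLOOR = 1e-6


def ar1_covariance(n: int, error: ErrorModel) -> np.ndarray:
    """AR(1) covariance over n ordered measurements: sigma^2 rho^|i-j|."""
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = np.arange(n)
    return error.sigma**2 * error.rho ** np.abs(idx[:, None] - idx[None, :])


def mean_gradient(
    t, params: CurveParameters, include_c: bool | None = None
) -> np.ndarray:
    """Gradient of the mean curve in the parameters, evaluated at time(s) t.

    Returns an array with last axis (d/dalpha, d/dbeta, d/dt_scale[, d/dc]).
    ``include_c=False`` drops the shift component and substitutes c = 0 (the
    simplified three-parameter model); the default infers the model from
    ``params.c``.  The closed forms use the digamma function psi for the
    shape derivatives:

        dmu/dalpha   = f(x) [ log x     - (psi(a) - psi(a+b)) ]
        dmu/dbeta    = f(x) [ log(1-x)  - (psi(b) - psi(a+b)) ]
        dmu/dt_scale = [ (b-1)(t+c) g_b - (a-1)(t+c) g_a ] / t_scale^2
        dmu/dc       = [ (a-1) g_a      - (b-1) g_b       ] / t_scale

    with x = (t+c)/t_scale, f the beta density and g_a, g_b the density
    kernels with the respective exponent lowered by one.
    """
    if include_c is None:
        include_c = params.c > 0
    a, b, ts = params.alpha, params.beta, params.t_scale
    c = params.c if include_c else 0.0
    t = np.asarray(t, dtype=float)
    if c == 0.0:
        t = np.maximum(t, _TIME_FLOOR)
    x = (t + c) / ts
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("scaled time (t + c)/t_scale must lie strictly in (0, 1)")
    log_x = np.log(x)
    log_1mx = np.log1p(-x)
    lB = betaln(a, b)
    f = np.exp((a - 1) * log_x + (b - 1) * log_1mx - lB)
    g_a = np.exp((a - 2) * log_x + (b - 1) * log_1mx - lB)  # x^(a-2)(1-x)^(b-1)/B
    g_b = np.exp((a - 1) * log_x + (b - 2) * log_1mx - lB)  # x^(a-1)(1-x)^(b-2)/B
    psi_ab = digamma(a + b)
    d_alpha = f * (log_x - (digamma(a) - psi_ab))
    d_beta = f * (log_1mx - (digamma(b) - psi_ab))
    d_ts = ((b - 1) * (t + c) * g_b - (a - 1) * (t + c) * g_a) / ts**2
    cols = [d_alpha, d_beta, d_ts]
    if include_c:
        cols.append(((a - 1) * g_a - (b - 1) * g_b) / ts)
    return np.stack(cols, axis=-1)


def fisher_information(
    design: Design,
    params: CurveParameters,
    error: ErrorModel,
    include_c: bool | None = None,
) -> np.ndarray:
    """Fisher information matrix J' Sigma^-1 J of a schedule.

    ``J`` stacks the mean gradient at each sampling time; ``Sigma`` is the
    index-based AR(1) covariance.  Symmetric positive semidefinite; singular
    whenever two sampling times coincide and n equals the number of
    parameters.
    """
    t = design.times_array
    J = np.atleast_2d(mean_gradient(t, params, include_c))
    sigma = ar1_covariance(len(t), error)
    solve = np.linalg.solve(sigma, J)
    fim = J.T @ solve
    return 0.5 * (fim + fim.T)


#: eigenvalue ratios below this are indistinguishable from round-off.
#: Duplicated-time designs give a smallest eigenvalue at +/-1e-20 of the
#: largest, while legitimate schedules - even for curves with a shift of
#: 1e-6 days, the worst-conditioned case among the presets - stay above
#: 1e-16.
_RANK_RTOL = 1e-18


def _det_psd(fim: np.ndarray) -> float:
    """Determinant of a (numerically) PSD matrix, zero when rank-deficient."""
    eig = np.linalg.eigvalsh(fim)
    if eig[-1] <= 0 or eig[0] <= _RANK_RTOL * eig[-1]:
        return 0.0
    return float(np.exp(np.sum(np.log(eig))))


def d_objective(
    design: Design, params: CurveParameters, error: ErrorModel,
    include_c: bool | None = None,
) -> float:
    """The scalar minimized by the schedule search: -ln(det(FIM) + 1).

    Equals 0 for any degenerate schedule (det(FIM) = 0) and decreases as the
    information determinant grows.
    """
    fim = fisher_information(design, params, error, include_c)
    return -float(np.log1p(_det_psd(fim)))


def d_efficiency(
    candidate: Design,
    reference_optimal: Design,
    params: CurveParameters,
    error: ErrorModel,
    include_c: bool | None = None,
) -> float:
    """Relative efficiency (det ratio)^(1/p) of a candidate schedule.

    Both schedules are scored under the *same* parameters (the true curve).
    A value of 0.5 means the candidate would need twice the subjects for the
    information yield of the reference.  Clipped into [0, 1]; a singular
    reference is an error since no valid optimum exists.
    """
    if include_c is None:
        include_c = params.c > 0
    p = 4 if include_c else 3
    det_ref = _det_psd(fisher_information(reference_optimal, params, error, include_c))
    if det_ref <= 0:
        raise ValueError("reference design has singular information matrix")
    det_cand = _det_psd(fisher_information(candidate, params, error, include_c))
    return float(np.clip((det_cand / det_ref) ** (1.0 / p), 0.0, 1.0))


class FastDObjective:
    """Pre-baked -ln(det(FIM)+1) evaluator for the inner optimizer loop.

    Freezes the parameter- and error-model-dependent constants (digamma and
    log-beta terms, the inverse covariance) so each call only touches the
    trial time vector.  Produces values identical to :func:`d_objective`.
    """

    def __init__(
        self,
        params: CurveParameters,
        error: ErrorModel,
        include_c: bool | None = None,
    ):
        if include_c is None:
            include_c = params.c > 0
        self.include_c = include_c
        self.p = 4 if include_c else 3
        self.a = params.alpha
        self.b = params.beta
        self.ts = params.t_scale
        self.c = params.c if include_c else 0.0
        self._lB = betaln(self.a, self.b)
        psi_ab = digamma(self.a + self.b)
        self._da = digamma(self.a) - psi_ab
        self._db = digamma(self.b) - psi_ab
        self._sigma_inv = np.linalg.inv(ar1_covariance(self.p, error))

    def gradient_matrix(self, times: np.ndarray) -> np.ndarray:
        a, b, ts, c = self.a, self.b, self.ts, self.c
        t = np.asarray(times, dtype=float)
        if c == 0.0:
            t = np.maximum(t, _TIME_FLOOR)
        x = (t + c) / ts
        log_x = np.log(x)
        log_1mx = np.log1p(-x)
        f = np.exp((a - 1) * log_x + (b - 1) * log_1mx - self._lB)
        g_a = np.exp((a - 2) * log_x + (b - 1) * log_1mx - self._lB)
        g_b = np.exp((a - 1) * log_x + (b - 2) * log_1mx - self._lB)
        cols = [
            f * (log_x - self._da),
            f * (log_1mx - self._db),
            ((b - 1) * (t + c) * g_b - (a - 1) * (t + c) * g_a) / ts**2,
        ]
        if self.include_c:
            cols.append(((a - 1) * g_a - (b - 1) * g_b) / ts)
        return np.stack(cols, axis=-1)

    def det_fim(self, times: np.ndarray) -> float:
        t = np.asarray(times, dtype=float)
        if self.c == 0.0:
            t = np.maximum(t, _TIME_FLOOR)
        x = (t + self.c) / self.ts
        if np.any(x <= 0) or np.any(x >= 1):
            # the gradient is undefined on the boundary of the scaled
            # domain (log singularities): no usable information there
            return 0.0
        J = self.gradient_matrix(t)
        fim = J.T @ self._sigma_inv @ J
        return _det_psd(0.5 * (fim + fim.T))

    def __call__(self, times: np.ndarray) -> float:
        return -float(np.log1p(self.det_fim(times)))
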