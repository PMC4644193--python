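"""Lifetime and amplitude recovery from phase/modulation curves.

The inverse problem of frequency-domain fluorometry: given a measured
phase (and optionally modulation) curve, estimate the lifetimes τ_k and
fractional amplitudes f_k of the multi-exponential transfer function

    F(iω) = Σ_k f_k / (1 + iωτ_k),  Σ f_k = 1.

Phase curves of mixtures are strongly non-linear in the parameters and
the least-squares surface is multimodal (a fast component "masks" the
slow component's phase at high frequency), so the fit is run from
multiple log-spaced starting lifetimes and parameterized without
constraints: log τ_k for positivity and a softmax over free logits for
the fractions.  By default only the phase enters the objective — the
modulation curve of a two-component mixture differs only subtly from a
single-exponential one and adds little leverage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .models import FrequencyResponse, MultiExpModel

__all__ = ["FitResult", "fit_lifetimes", "mixture_phase_family"]


@dataclass
class FitResult:
    """Point estimate, covariance, and diagnostics of a lifetime fit.

    ``covariance`` is over the internal parameters, ordered
    (log τ_1..n, logit f_2..n), for the component order of ``model``
    (lifetimes sorted descending).
    """

    model: MultiExpModel
    covariance: np.ndarray
    param_names: tuple[str, ...]
    objective: float
    residual_rms: float
    n_points: int
    n_iter: int
    converged: bool
    messages: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "lifetimes_s": [tau for _, tau in self.model.components],
            "fractions": [f for f, _ in self.model.components],
            "covariance": self.covariance.tolist(),
            "param_names": list(self.param_names),
            "objective": self.objective,
            "residual_rms": self.residual_rms,
            "n_points": self.n_points,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "messages": list(self.messages),
        }

    def lifetime_se_log(self) -> np.ndarray:
        """Standard errors of log-lifetimes (diagonal of the covariance)."""
        n = len(self.model.components)
        return np.sqrt(np.diag(self.covariance)[:n])


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = np.concatenate([[0.0], logits])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _unpack(theta: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    taus = np.exp(theta[:n])
    fracs = _softmax(theta[n:]) if n > 1 else np.array([1.0])
    return taus, fracs


def _predict(theta: np.ndarray, n: int, omega: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    taus, fracs = _unpack(theta, n)
    h = (fracs / (1.0 + 1j * np.multiply.outer(omega, taus))).sum(axis=-1)
    phase = -np.degrees(np.angle(h))
    mod = np.abs(h)  # fractions sum to 1, so |F(0)| = 1
    return phase, mod


def fit_lifetimes(
    curve: FrequencyResponse,
    n_components: int,
    use: str = "phase",
    n_starts: int = 8,
    seed: int = 0,
    max_nfev: int = 2000,
) -> FitResult:
    """Weighted nonlinear least squares for lifetimes and fractions.

    ``use`` selects the observables entering the objective: "phase",
    "mod", or "both".  Weights are 1/sd² when the curve carries standard
    deviations.  Starting lifetimes are drawn log-uniformly over the
    reciprocal of the curve's frequency span (``n_starts`` restarts with
    a fixed ``seed``, plus one deterministic log-spaced start); the best
    local optimum is returned with its covariance (inverse Gauss-Newton
    Hessian scaled by the residual variance).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if use not in ("phase", "mod", "both"):
        raise ValueError("use must be 'phase', 'mod' or 'both'")
    n_params = 2 * n_components - 1
    m_obs = len(curve) * (2 if use == "both" else 1)
    if len(curve) < 2 * n_params:
        raise ValueError(
            f"curve has {len(curve)} points; fitting {n_components} components "
            f"({n_params} parameters) needs at least {2 * n_params}"
        )
    omega = curve.frequencies
    span = omega.max() / omega.min()
    if n_components > 1 and span < 10.0 ** (n_components - 1):
        raise ValueError(
            f"curve spans only a factor {span:.3g} in frequency; "
            f"{n_components} components are not identifiable on it"
        )

    obs, sds = [], []
    if use in ("phase", "both"):
        obs.append(curve.phase_deg)
        sds.append(curve.phase_sd)
    if use in ("mod", "both"):
        obs.append(curve.mod)
        sds.append(curve.mod_sd)

    weights = []
    for o, sd in zip(obs, sds):
        if sd is not None and np.all(np.isfinite(sd)) and np.all(sd > 0):
            weights.append(1.0 / sd)
        else:
            weights.append(np.ones_like(o))

    def residuals(theta):
        phase, mod = _predict(theta, n_components, omega)
        pred = []
        if use in ("phase", "both"):
            pred.append(phase)
        if use in ("mod", "both"):
            pred.append(mod)
        return np.concatenate([(p - o) * w for p, o, w in zip(pred, obs, weights)])

    # starting points: one deterministic log-spaced set plus seeded draws
    rng = np.random.default_rng(seed)
    log_lo, log_hi = math.log(0.1 / omega.max()), math.log(10.0 / omega.min())
    starts = [np.linspace(log_hi, log_lo, n_components)]
    for _ in range(max(0, n_starts - 1)):
        s = np.sort(rng.uniform(log_lo, log_hi, n_components))[::-1]
        starts.append(s)

    # keep lifetimes inside a generous window around the probed band
    lb = np.concatenate([np.full(n_components, log_lo - math.log(100.0)),
                         np.full(n_components - 1, -30.0)])
    ub = np.concatenate([np.full(n_components, log_hi + math.log(100.0)),
                         np.full(n_components - 1, 30.0)])

    best = None
    for s in starts:
        x0 = np.concatenate([s, np.zeros(n_components - 1)])
        try:
            res = least_squares(
                residuals, x0, bounds=(lb, ub), max_nfev=max_nfev, x_scale="jac"
            )
        except Exception:  # singular steps from degenerate starts
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("lifetime fit failed to converge from every start")

    taus, fracs = _unpack(best.x, n_components)
    messages: list[str] = []
    if np.any(fracs < 1e-4):
        messages.append(
            "a fitted fraction is below 1e-4: the component is not supported by the data"
        )
        warnings.warn(messages[-1], stacklevel=2)
    if np.any(taus < math.exp(log_lo)) or np.any(taus > math.exp(log_hi)):
        messages.append(
            "a fitted lifetime lies outside the curve's probed band; "
            "treat it as unidentified"
        )

    # covariance of internal parameters from the Gauss-Newton Hessian
    jac = best.jac
    dof = max(m_obs - n_params, 1)
    s2 = 2.0 * best.cost / dof
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * s2
        messages.append("covariance from pseudo-inverse: near-singular fit")
    cov = 0.5 * (cov + cov.T)

    # report with lifetimes sorted descending; permute covariance to match
    order = np.argsort(-taus)
    perm = np.concatenate([order, n_components + np.arange(n_components - 1)])
    # fraction logits are relative to component 0; re-deriving a permuted
    # logit covariance exactly would require a reparameterization, so the
    # logit block is left in fit order (documented in param_names).
    cov_sorted = cov[np.ix_(perm, perm)]
    model = MultiExpModel([(float(fracs[i]), float(taus[i])) for i in order])
    names = tuple(f"log_tau_{i}" for i in range(n_components)) + tuple(
        f"logit_f_{i}" for i in range(1, n_components)
    )
    resid = residuals(best.x)
    return FitResult(
        model=model,
        covariance=cov_sorted,
        param_names=names,
        objective=float(best.cost),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=len(curve),
        n_iter=int(best.nfev),
        converged=bool(best.success),
        messages=tuple(messages),
    )


def mixture_phase_family(
    fractions: "list[float]", tau_slow: float, tau_fast: float, omega: np.ndarray
) -> dict[float, np.ndarray]:
    """Phase curves of two-component mixtures over a grid of slow fractions.

    For each slow-component amplitude fraction ``f`` the phase of
    ``f/(1+iωτ_slow) + (1-f)/(1+iωτ_fast)`` is evaluated on ``omega``.
    Beyond the slow component's knee the curves are ordered: more fast
    component means less phase, because the demodulated slow emission is
    masked by the still-in-phase fast emission.
    """
    if not tau_slow > tau_fast > 0:
        raise ValueError("need tau_slow > tau_fast > 0")
    omega = np.asarray(omega, dtype=float)
    out: dict[float, np.ndarray] = {}
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        h = f / (1.0 + 1j * omega * tau_slow) + (1.0 - f) / (1.0 + 1j * omega * tau_fast)
        out[float(f)] = -np.degrees(np.angle(h))
    return out
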