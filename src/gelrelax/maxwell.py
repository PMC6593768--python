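"""Generalized Maxwell (Prony-series) fitting of stress-relaxation curves.

The relaxing stiffness of a viscoelastic gel held at constant strain is
modelled as a parallel combination of Maxwell elements, each a spring
(stiffness E_i) in series with a dashpot (relaxation time tau_i), plus an
optional equilibrium spring E_inf:

    E(t) = E_inf + sum_i E_i * exp(-t / tau_i)

Fitting starts with one element and adds elements until the decrease in the
chi-squared error (unweighted sum of squared residuals) becomes
insignificant; each element's share of the summed element stiffnesses is its
relative importance, RI_i = 100 * E_i / sum_j E_j. Elements are reported in
ascending tau order, so the "first" element is the fastest. A tau taxonomy
separates sub-second fluid expulsion, the 1-10 s ECM network response, and
slow 10-100 s modes; gels that cannot sustain the hold (collapse) are
flagged and excluded from cohort statistics.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .errors import GelRelaxError, UndefinedRIError
from .mechanics import RelaxationCurve

TAU_BINS = (
    ((0.0, 1.0), "sub_second_fluid"),
    ((1.0, 10.0), "ecm_1_10s"),
    ((10.0, 100.0), "slow_10_100s"),
    ((100.0, np.inf), "out_of_range"),
)


@dataclasses.dataclass
class MaxwellElement:
    """One spring-dashpot pair: stiffness E_i (kPa) and time constant tau_i (s)."""

    E_kpa: float
    tau_s: float

    def __post_init__(self) -> None:
        if self.E_kpa < 0:
            raise GelRelaxError(f"element stiffness {self.E_kpa} < 0")
        if self.tau_s <= 0:
            raise GelRelaxError(f"time constant {self.tau_s} <= 0")


@dataclasses.dataclass
class MaxwellFit:
    """A fitted Prony series with its order-selection history."""

    elements: list[MaxwellElement]
    E_inf_kpa: float
    chi2: float
    n_elements: int
    relative_importance: list[float]
    converged: bool
    selection_trace: list[tuple[int, float]]
    seed: int


@dataclasses.dataclass
class FitOptions:
    """Knobs of the nonlinear least-squares fit.

    tau starts log-spaced over ``tau_init_range`` (the decade range observed
    for these gels) and the optimiser is restarted ``n_starts`` times with
    seeded log-normal jitter; bounds keep E_i >= 0 and tau within
    ``tau_bounds``. ``fit_e_inf`` leaves the equilibrium stiffness free
    (bounded at 0); setting it False pins E_inf = 0. ``weights`` is a hook
    for per-sample residual weighting, off by default.
    """

    n_starts: int = 8
    tau_init_range: tuple[float, float] = (0.1, 100.0)
    tau_bounds: tuple[float, float] = (1e-3, 1e4)
    fit_e_inf: bool = True
    jitter_sigma: float = 0.5
    weights: np.ndarray | None = None
    max_nfev: int | None = None


@dataclasses.dataclass
class QCResult:
    collapsed: bool
    reasons: list[str]


def prony_predict(
    elements: Sequence[MaxwellElement], e_inf_kpa: float, t: np.ndarray
) -> np.ndarray:
    """Evaluate E(t) = E_inf + sum E_i exp(-t/tau_i) in kPa."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, float(e_inf_kpa))
    for el in elements:
        if el.tau_s <= 0:
            raise GelRelaxError("time constant must be positive")
        out = out + el.E_kpa * np.exp(-t / el.tau_s)
    return out


def chi_squared(fit: MaxwellFit, curve: RelaxationCurve) -> float:
    """Unweighted sum of squared residuals between the model and E(t)."""
    model = prony_predict(fit.elements, fit.E_inf_kpa, curve.t_s)
    return float(np.sum((curve.Et_kpa - model) ** 2))


def relative_importance(fit: MaxwellFit) -> list[float]:
    """RI_i = 100 * E_i / sum_j E_j (equilibrium term excluded)."""
    e = np.array([el.E_kpa for el in fit.elements], dtype=float)
    total = e.sum()
    if total <= 0:
        raise UndefinedRIError("all element stiffnesses are zero")
    return list(100.0 * e / total)


def classify_elements(fit: MaxwellFit) -> list[str]:
    """Label each element by its tau bin; bins are left-closed ([1,10) etc.)."""
    labels = []
    for el in fit.elements:
        for (lo, hi), label in TAU_BINS:
            # final bin is open above 100 s; [10, 100] is closed at 100
            if lo < el.tau_s < hi or (lo > 0 and el.tau_s == lo) or (hi == 100.0 and el.tau_s == hi):
                labels.append(label)
                break
        else:
            labels.append("out_of_range")
    return labels


def _residual_fn(curve: RelaxationCurve, n: int, fit_e_inf: bool, weights):
    t, y = curve.t_s, curve.Et_kpa
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, dtype=float))

    def residuals(x):
        e, tau = x[:n], x[n : 2 * n]
        e_inf = x[2 * n] if fit_e_inf else 0.0
        model = e_inf + np.exp(-t[:, None] / tau[None, :]) @ e
        return w * (model - y)

    return residuals


def _pack(elements: Sequence[MaxwellElement], e_inf: float, n: int, fit_e_inf: bool):
    """Parameter vector reproducing a lower-order fit, padded with
    zero-stiffness elements placed in the largest log-gap of the taus."""
    pairs = [(el.E_kpa, el.tau_s) for el in elements]
    while len(pairs) < n:
        existing = np.sort([tau for _, tau in pairs]) if pairs else np.asarray([])
        candidates = np.concatenate([[0.05], existing, [200.0]])
        gaps = np.diff(np.log(candidates))
        k = int(np.argmax(gaps))
        pairs.append((0.0, float(np.sqrt(candidates[k] * candidates[k + 1]))))
    pairs.sort(key=lambda p: p[1])
    e = [p[0] for p in pairs]
    tau = [p[1] for p in pairs]
    return np.array(e + tau + ([e_inf] if fit_e_inf else []), dtype=float)


def fit_fixed_order(
    curve: RelaxationCurve,
    n: int,
    options: FitOptions | None = None,
    seed: int = 0,
    warm_start: MaxwellFit | None = None,
) -> MaxwellFit:
    """Fit an n-element Prony series by bounded multi-start least squares.

    Starts from log-spaced taus over the observed decade range with
    E_i = E(0)/n, plus seeded jittered restarts (and, when given, the
    previous-order solution padded with a zero-stiffness element, which
    guarantees the chi-squared can only improve with order). Deterministic
    for a given seed. A fit that never converges is returned flagged
    (``converged=False``), never silently.
    """
    opts = options or FitOptions()
    if n < 1:
        raise GelRelaxError("need at least one element")
    if len(curve) <= 3 * n + 1:
        raise GelRelaxError(f"curve has too few samples ({len(curve)}) for n={n}")

    t, y = curve.t_s, curve.Et_kpa
    y0 = max(float(y[0]), 1e-12)
    yend = max(float(y[-1]), 0.0)
    rng = np.random.default_rng(seed)
    residuals = _residual_fn(curve, n, opts.fit_e_inf, opts.weights)

    lo_tau, hi_tau = opts.tau_bounds
    lower = np.concatenate([np.zeros(n), np.full(n, lo_tau), [0.0] if opts.fit_e_inf else []])
    upper = np.concatenate(
        [np.full(n, np.inf), np.full(n, hi_tau), [np.inf] if opts.fit_e_inf else []]
    )

    tau0 = np.geomspace(*opts.tau_init_range, n) if n > 1 else np.array(
        [float(np.sqrt(opts.tau_init_range[0] * opts.tau_init_range[1]))]
    )
    e_inf0 = yend if opts.fit_e_inf else 0.0
    e0 = np.full(n, max(y0 - e_inf0, 0.1 * y0) / n)

    starts = [np.concatenate([e0, tau0, [e_inf0] if opts.fit_e_inf else []])]
    for _ in range(opts.n_starts - 1):
        jit_tau = tau0 * np.exp(rng.normal(0, opts.jitter_sigma, n))
        jit_e = e0 * np.exp(rng.normal(0, opts.jitter_sigma, n))
        jit_einf = [e_inf0 * np.exp(rng.normal(0, opts.jitter_sigma))] if opts.fit_e_inf else []
        starts.append(np.concatenate([jit_e, np.clip(jit_tau, lo_tau, hi_tau), jit_einf]))
    if warm_start is not None and warm_start.n_elements < n:
        starts.insert(
            0, _pack(warm_start.elements, warm_start.E_inf_kpa, n, opts.fit_e_inf)
        )

    best_x, best_cost, converged = None, np.inf, False
    for x0 in starts:
        x0 = np.clip(x0, lower, np.where(np.isinf(upper), x0, upper))
        try:
            sol = least_squares(
                residuals, x0, bounds=(lower, upper), method="trf", max_nfev=opts.max_nfev
            )
        except Exception:
            continue
        cost = float(np.sum(sol.fun**2))
        if sol.status > 0 and cost < best_cost:
            best_x, best_cost, converged = sol.x, cost, True
    if best_x is None:
        best_x = starts[0]
        best_cost = float(np.sum(residuals(best_x) ** 2))

    e, tau = best_x[:n], best_x[n : 2 * n]
    e_inf = float(best_x[2 * n]) if opts.fit_e_inf else 0.0
    order = np.argsort(tau)
    elements = [MaxwellElement(float(e[i]), float(tau[i])) for i in order]
    fit = MaxwellFit(
        elements=elements,
        E_inf_kpa=e_inf,
        chi2=best_cost,
        n_elements=n,
        relative_importance=[],
        converged=converged,
        selection_trace=[(n, best_cost)],
        seed=seed,
    )
    if sum(el.E_kpa for el in elements) > 0:
        fit.relative_importance = relative_importance(fit)
    return fit


def select_order(
    curve: RelaxationCurve,
    max_n: int = 4,
    epsilon: float = 0.05,
    options: FitOptions | None = None,
    seed: int = 0,
    criterion: str = "chi2_rel",
) -> MaxwellFit:
    """Add Maxwell elements until the chi-squared improvement is insignificant.

    With the default relative-improvement criterion, fitting stops at the
    first order n where (chi2_n - chi2_{n+1}) / chi2_n < epsilon; the
    alternative ``criterion="f_test"`` stops when the extra-sum-of-squares
    F test for the added element is not significant at 0.05. The returned
    fit carries the full (n, chi2) selection trace, which is non-increasing
    in n because each order is warm-started from the previous solution.
    """
    if max_n < 1:
        raise GelRelaxError("max_n must be >= 1")
    opts = options or FitOptions()
    # chi2 at machine precision relative to the data scale counts as perfect
    floor = 1e-12 * float(np.sum(np.asarray(curve.Et_kpa) ** 2))
    fits = [fit_fixed_order(curve, 1, opts, seed=seed)]
    trace = [(1, fits[0].chi2)]
    chosen = fits[0]
    for n in range(1, max_n):
        prev = fits[-1]
        if prev.chi2 <= floor:
            break
        nxt = fit_fixed_order(curve, n + 1, opts, seed=seed + n, warm_start=prev)
        # warm start guarantees chi2 can only improve; guard against the
        # optimiser returning a worse local solution anyway
        if nxt.chi2 > prev.chi2:
            nxt = dataclasses.replace(nxt, chi2=prev.chi2, elements=list(prev.elements)
                                      + [MaxwellElement(0.0, nxt.elements[-1].tau_s)],
                                      E_inf_kpa=prev.E_inf_kpa)
        fits.append(nxt)
        trace.append((n + 1, nxt.chi2))
        if criterion == "f_test":
            npt = len(curve)
            dof_extra = 2  # one E and one tau per added element
            dof_resid = npt - (2 * (n + 1) + (1 if opts.fit_e_inf else 0))
            if nxt.chi2 <= 0 or dof_resid <= 0:
                stop = nxt.chi2 >= prev.chi2
            else:
                F = ((prev.chi2 - nxt.chi2) / dof_extra) / (nxt.chi2 / dof_resid)
                stop = float(f_dist.sf(F, dof_extra, dof_resid)) > 0.05
        else:
            stop = (prev.chi2 - nxt.chi2) / prev.chi2 < epsilon
        if stop:
            chosen = prev
            break
        chosen = nxt
    chosen = dataclasses.replace(chosen, selection_trace=trace)
    if sum(el.E_kpa for el in chosen.elements) > 0:
        chosen.relative_importance = relative_importance(chosen)
    return chosen


def qc_flag_collapse(curve: RelaxationCurve, fit: MaxwellFit | None = None) -> QCResult:
    """Flag measurements where the gel collapsed during the hold.

    A collapse is declared when any of: the relaxing stiffness sits at or
    below zero for a substantial part (>=10% of samples) of the first tenth
    of the hold — these gels legitimately relax toward zero within tens of
    seconds, so isolated noise dips below zero late in that window must not
    fire the flag, but a collapsed gel's signal drops to baseline and stays
    there; an adjacent-sample drop exceeds 50% of the local stiffness (away
    from the noise floor); or the fit failed to converge at every order.
    Flagged samples are excluded from cohort aggregation.
    """
    reasons: list[str] = []
    et = curve.Et_kpa
    t = curve.t_s
    t_end = t[-1] if t.size else 0.0
    if et.size == 0 or et[0] <= 0:
        return QCResult(True, ["non-positive initial stiffness"])
    early = t <= 0.1 * t_end
    if np.mean(et[early] <= 0) >= 0.1:
        reasons.append("stiffness at/below zero through the early hold")
    # only consider drops well above the noise floor: a halving of E(t) is
    # only evidence of collapse while the signal is still substantial
    floor = 0.1 * et[0]
    prev, nxt = et[:-1], et[1:]
    if np.any((prev > floor) & (prev - nxt > 0.5 * np.maximum(prev, 0))):
        reasons.append("abrupt >50% drop between adjacent samples")
    if fit is not None and not fit.converged:
        reasons.append("fit failed to converge at all orders")
    return QCResult(bool(reasons), reasons)
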