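"""Cooperative hemoglobin-O2 binding/unbinding kinetics.

A four-step sequential (Adair-type) scheme:

    Hb(O2)_0  <->  Hb(O2)_1  <->  Hb(O2)_2  <->  Hb(O2)_3  <->  Hb(O2)_4

with per-site intrinsic rate constants and the usual statistical factors
(state ``i`` loses O2 at total rate ``i * k_off_i`` and binds at
``(4 - i) * k_on_{i+1} * [O2]``).  Unbinding of the first O2 from
oxyhemoglobin is slow (k_d ~20-30 s^-1); cooperativity makes the later
unbinding steps faster, so the ensemble dissociation rate of the whole
tetramer can approach ~100 s^-1.  The ensemble rate is defined here as the
rate constant of the equal-area single exponential of the zero-O2
dissociation cascade, which for per-site off-rates ``k_i`` has the closed
form ``4 / sum_i(1/k_i)`` (harmonic mean); with no cooperativity it equals
``k_d_first`` exactly, and it is bounded above by ``4 * k_d_first``.

Equilibrium is the generalized Adair curve

    S(x) = (x/4) P'(x) / P(x),   P(x) = sum_i C(4,i) (prod_{j<=i} a_j) x^i

with per-site association constants ``a_j = k_on_j / k_off_j`` calibrated
so that the curve reproduces the configured (p50, hill_n): S(p50) = 0.5
exactly and the logit slope at p50 within 1%, while tracking the
idealized Hill curve pointwise over 1-150 mmHg (typical maximum absolute
deviation ~0.01; a four-constant Adair scheme cannot be an exact Hill
function, so the pointwise deviation is a diagnostic, not a contract).

Units: rates s^-1; association rates uM^-1 s^-1; free O2 converted from
partial pressure with a fixed solubility (default 1.3 uM/mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, least_squares

from .errors import DomainError, ParameterizationError

#: O2 solubility used to convert mmHg to uM free O2.
O2_SOLUBILITY_UM_PER_MMHG = 1.3

#: molar mass of the hemoglobin monomer (one heme site), g/mol
HB_MONOMER_G_PER_MOL = 16114.0

#: default equilibrium parameters (configurable; see methods note)
DEFAULT_P50_MMHG = 26.0
DEFAULT_HILL_N = 2.7
DEFAULT_MCHC_G_PER_L = 330.0

_BINOM = np.array([1.0, 4.0, 6.0, 4.0, 1.0])


def heme_concentration_mM(mchc: float) -> float:
    """Total heme (O2-binding site) concentration from MCHC (g/L) -> mM."""
    if mchc <= 0:
        raise DomainError("mchc must be positive")
    return mchc / HB_MONOMER_G_PER_MOL * 1000.0


@dataclass(frozen=True)
class HbO2Scheme:
    """Calibrated four-step sequential Hb-O2 scheme.

    ``k_d_first`` is the per-site off-rate of the first unbinding step
    (from the fully saturated tetramer); ``cooperativity_factors`` multiply
    the per-site off-rates of steps 2-4.  ``assoc_site`` are the per-site
    association equilibrium constants a_j (uM^-1) for binding steps
    j = 1..4 (so the off-rate of step j pairs with a_j).
    """

    k_d_first: float
    cooperativity_factors: tuple[float, float, float]
    assoc_site: tuple[float, float, float, float]
    p50: float
    hill_n: float
    heme_total: float  # mM
    co2_affinity_factor: float = 1.0
    solubility: float = O2_SOLUBILITY_UM_PER_MMHG

    def __post_init__(self):
        if self.k_d_first <= 0:
            raise DomainError("k_d_first must be positive")
        if len(self.cooperativity_factors) != 3 or any(
            c < 1.0 for c in self.cooperativity_factors
        ):
            raise DomainError("cooperativity factors must be >= 1 (length 3)")
        if any(a <= 0 for a in self.assoc_site):
            raise DomainError("association constants must be positive")

    # per-site off-rates for dissociation steps j=4,3,2,1 map to k_off[j]
    @property
    def k_off_site(self) -> np.ndarray:
        """Per-site off-rates, indexed by binding step j=1..4 (array[ j-1 ])."""
        c1, c2, c3 = self.cooperativity_factors
        # step 4 (first unbinding) = k_d_first; steps 3,2,1 faster
        return np.array(
            [self.k_d_first * c3, self.k_d_first * c2, self.k_d_first * c1,
             self.k_d_first]
        )

    @property
    def k_on(self) -> np.ndarray:
        """Per-site association rate constants (uM^-1 s^-1), steps 1..4."""
        return np.asarray(self.assoc_site) * self.k_off_site

    def free_o2_uM(self, pO2: float | np.ndarray) -> float | np.ndarray:
        return self.solubility * np.asarray(pO2, dtype=float)

    def binding_polynomial(self, x_uM):
        """P(x) and x P'(x) for free O2 ``x`` in uM."""
        a = np.asarray(self.assoc_site)
        coeff = _BINOM * np.concatenate(([1.0], np.cumprod(a)))
        x = np.asarray(x_uM, dtype=float)
        powers = x[..., None] ** np.arange(5)
        P = powers @ coeff
        xPp = powers @ (coeff * np.arange(5))
        return P, xPp

    def equilibrium_occupancies(self, pO2: float) -> np.ndarray:
        """Equilibrium fractions of Hb(O2)_0..4 at the given pO2."""
        x = float(self.free_o2_uM(pO2))
        a = np.asarray(self.assoc_site)
        w = _BINOM * np.concatenate(([1.0], np.cumprod(a))) * x ** np.arange(5)
        return w / w.sum()


def equilibrium_saturation(scheme: HbO2Scheme, pO2) -> float | np.ndarray:
    """Fractional O2 saturation of Hb at equilibrium with the given pO2."""
    p = np.asarray(pO2, dtype=float)
    if np.any(p < 0):
        raise DomainError("pO2 must be nonnegative")
    x = scheme.free_o2_uM(p)
    P, xPp = scheme.binding_polynomial(x)
    sat = xPp / (4.0 * P)
    return float(sat) if np.isscalar(pO2) else sat


def ensemble_kd(scheme: HbO2Scheme) -> float:
    """Ensemble dissociation rate of the tetramer in zero free O2.

    Rate constant of the equal-area single exponential of the bound-O2
    relaxation; harmonic mean of the per-site off-rates.
    """
    return 4.0 / float(np.sum(1.0 / scheme.k_off_site))


def simulate_relaxation(
    scheme: HbO2Scheme,
    duration: float | None = None,
    n_times: int = 400,
    initial_occupancies=None,
):
    """Well-mixed relaxation of saturated Hb placed in zero free O2 with a
    perfect O2 sink (no rebinding).  Returns (time, saturation).

    Starts fully saturated unless ``initial_occupancies`` (fractions of
    states 0..4) is given.  Serves as the kinetic oracle for
    :func:`ensemble_kd`.
    """
    kens = ensemble_kd(scheme)
    if duration is None:
        duration = 6.0 / kens
    koff = scheme.k_off_site  # index j-1 for step j

    def rhs(_t, y):
        # y: occupancy fractions of states 0..4
        dy = np.zeros(5)
        for j in range(4, 0, -1):  # state j -> j-1 at rate j * k_off[j-1]
            r = j * koff[j - 1] * y[j]
            dy[j] -= r
            dy[j - 1] += r
        return dy

    if initial_occupancies is None:
        y0 = np.array([0, 0, 0, 0, 1.0])
    else:
        y0 = np.asarray(initial_occupancies, dtype=float)
    t_eval = np.linspace(0, duration, n_times)
    sol = solve_ivp(rhs, (0, duration), y0, t_eval=t_eval, method="LSODA",
                    rtol=1e-9, atol=1e-12)
    sat = (sol.y.T @ np.arange(5)) / 4.0
    return sol.t, sat


def _hill(p, p50, n):
    r = (np.asarray(p, dtype=float) / p50) ** n
    return r / (1.0 + r)


def _calibrate_assoc(p50: float, hill_n: float, solubility: float):
    """Per-site association constants a_j reproducing (p50, hill_n)."""
    x50 = solubility * p50
    grid = np.geomspace(1.0, 150.0, 200)
    target = _hill(grid, p50, hill_n)
    xg = solubility * grid

    def assoc_of(v):
        # monotone nondecreasing per-site affinity ladder (positive
        # cooperativity): a_j = exp(v0 + sum of nonnegative increments)/x50
        la = v[0] + np.concatenate(([0.0], np.cumsum(v[1:])))
        return np.exp(la) / x50

    def sat_of(v, x):
        a = assoc_of(v)
        coeff = _BINOM * np.concatenate(([1.0], np.cumprod(a)))
        powers = np.asarray(x)[:, None] ** np.arange(5)
        P = powers @ coeff
        xPp = powers @ (coeff * np.arange(5))
        return xPp / (4.0 * P)

    def slope_at_p50(v_or_a, is_a=False):
        xs = x50 * np.array([0.995, 1.005])
        if is_a:
            a = v_or_a
            coeff = _BINOM * np.concatenate(([1.0], np.cumprod(a)))
            powers = xs[:, None] ** np.arange(5)
            S = (powers @ (coeff * np.arange(5))) / (4.0 * (powers @ coeff))
        else:
            S = sat_of(v_or_a, xs)
        return float((np.diff(np.log(S / (1 - S))) / np.diff(np.log(xs)))[0])

    def residuals(v):
        res = sat_of(v, xg) - target
        # strongly pin the logit slope at p50 to the Hill coefficient and
        # the half-saturation point itself; the pointwise agreement with
        # the idealized Hill curve is a soft objective
        slope = slope_at_p50(v)
        pin = sat_of(v, np.array([x50]))[0] - 0.5
        return np.concatenate([res, [8.0 * (slope - hill_n) / hill_n,
                                     10.0 * pin]])

    # initial guess: geometric ladder of per-site affinities around 1/x50
    lr = np.log(8.0) * (hill_n - 1.0) / 3.0
    v0 = np.array([-1.5 * lr, lr, lr, lr])
    fit = least_squares(residuals, v0,
                        bounds=([-8.0, -4.0, -4.0, -4.0], [4.0, 6.0, 6.0, 6.0]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    a = assoc_of(fit.x)

    # pin S(p50) = 0.5 exactly by a uniform rescale (equivalent to x -> lam*x)
    def s_at(lam):
        coeff = _BINOM * np.concatenate(([1.0], np.cumprod(a * lam)))
        powers = x50 ** np.arange(5)
        P = powers @ coeff
        xPp = powers @ (coeff * np.arange(5))
        return xPp / (4.0 * P) - 0.5

    lam = brentq(s_at, 1e-3, 1e3, xtol=1e-15, rtol=8.9e-16)
    a = a * lam

    coeff = _BINOM * np.concatenate(([1.0], np.cumprod(a)))
    powers = xg[:, None] ** np.arange(5)
    achieved = (powers @ (coeff * np.arange(5))) / (4.0 * (powers @ coeff))
    diag = {
        "max_abs_saturation_dev": float(np.max(np.abs(achieved - target))),
        "hill_slope_at_p50": slope_at_p50(a, is_a=True),
    }
    return tuple(a), diag


def build_scheme(
    k_d_first: float,
    ensemble_kd_target: float,
    p50: float = DEFAULT_P50_MMHG,
    hill_n: float = DEFAULT_HILL_N,
    mchc: float = DEFAULT_MCHC_G_PER_L,
    solubility: float = O2_SOLUBILITY_UM_PER_MMHG,
) -> HbO2Scheme:
    """Calibrate a four-step scheme to (p50, hill_n) and an ensemble rate.

    Cooperativity is realized as a common geometric ladder on the per-site
    off-rates of steps 3, 2, 1 (factors g, g^2, g^3 with g >= 1), solved so
    the ensemble rate (harmonic mean of per-site off-rates) hits the
    target; the equilibrium curve is calibrated to S(p50) = 0.5 and the
    configured Hill slope at p50 (within 1%).  The ensemble rate of this scheme class is bounded by
    ``4 * k_d_first``; an unreachable target raises
    :class:`ParameterizationError` with a diagnostic.
    """
    if k_d_first <= 0:
        raise DomainError("k_d_first must be positive")
    if ensemble_kd_target < k_d_first:
        raise DomainError("ensemble_kd_target must be >= k_d_first")
    if p50 <= 0 or hill_n < 1:
        raise DomainError("require p50 > 0 and hill_n >= 1")
    if mchc <= 0:
        raise DomainError("mchc must be positive")

    ceiling = 4.0 * k_d_first
    if ensemble_kd_target >= 0.999 * ceiling and ensemble_kd_target > k_d_first:
        raise ParameterizationError(
            f"ensemble target {ensemble_kd_target} s^-1 unreachable: the "
            f"four-step cascade with first-step off-rate {k_d_first} s^-1 is "
            f"bounded by 4*k_d_first = {ceiling} s^-1",
            diagnostic={"k_d_first": k_d_first,
                        "target": ensemble_kd_target,
                        "ceiling": ceiling},
        )

    if ensemble_kd_target == k_d_first:
        g = 1.0
    else:
        # ensemble(g) = 4 k1 / (1 + 1/g + 1/g^2 + 1/g^3), solve for g
        def f(logg):
            g_ = np.exp(logg)
            return 4.0 * k_d_first / (1 + 1 / g_ + 1 / g_**2 + 1 / g_**3) \
                - ensemble_kd_target
        g = float(np.exp(brentq(f, 0.0, 40.0, xtol=1e-12)))

    factors = (g, g**2, g**3)
    assoc, diag = _calibrate_assoc(p50, hill_n, solubility)
    slope = diag["hill_slope_at_p50"]
    if abs(slope - hill_n) / hill_n > 0.01 or diag["max_abs_saturation_dev"] > 0.05:
        raise ParameterizationError(
            f"equilibrium calibration failed for (p50={p50}, hill_n={hill_n}): "
            f"achieved Hill slope {slope:.3f}, max saturation deviation "
            f"{diag['max_abs_saturation_dev']:.3f} from the idealized curve",
            diagnostic=diag,
        )
    return HbO2Scheme(
        k_d_first=k_d_first,
        cooperativity_factors=factors,
        assoc_site=assoc,
        p50=p50,
        hill_n=hill_n,
        heme_total=heme_concentration_mM(mchc),
        solubility=solubility,
    )


#: default ensemble/first-step ratio of the cooperative ladder: first-step
#: rates of 20-30 s^-1 then give ensemble rates of 70-105 s^-1 (~100 s^-1)
DEFAULT_ENSEMBLE_RATIO = 3.5


def scheme_for_kd(
    kd_first: float,
    ensemble_ratio: float = DEFAULT_ENSEMBLE_RATIO,
    p50: float = DEFAULT_P50_MMHG,
    hill_n: float = DEFAULT_HILL_N,
    mchc: float = DEFAULT_MCHC_G_PER_L,
    solubility: float = O2_SOLUBILITY_UM_PER_MMHG,
) -> HbO2Scheme:
    """Cooperative scheme parameterized by its first-step dissociation rate.

    Later unbinding steps are always faster (cooperativity is a structural
    feature of the Hb tetramer, not a free knob), with the ladder fixed so
    the ensemble rate is ``ensemble_ratio * kd_first``; ``ensemble_ratio=1``
    recovers the cooperativity-free limiting case.
    """
    return build_scheme(kd_first, ensemble_ratio * kd_first, p50=p50,
                        hill_n=hill_n, mchc=mchc, solubility=solubility)


def apply_co2_correction(scheme: HbO2Scheme, factor: float) -> HbO2Scheme:
    """Scale every step's equilibrium association constant by ``factor``.

    Each per-site a_j is multiplied by ``factor`` (0 < f <= 1), implemented
    by scaling the on-rates; this shifts the whole equilibrium curve along
    the pO2 axis, so p50 rises exactly by 1/factor.  Models the reduced
    Hb-O2 affinity at physiological CO2 (factor 0.949 for 40 mmHg P_CO2);
    the factor is recorded in provenance.
    """
    if not (0 < factor <= 1):
        raise DomainError("co2 affinity factor must be in (0, 1]")
    if factor == 1.0:
        return scheme
    new_assoc = tuple(a * factor for a in scheme.assoc_site)
    # uniform per-site scaling is exactly the substitution x -> factor*x
    return replace(scheme, assoc_site=new_assoc, p50=scheme.p50 / factor,
                   co2_affinity_factor=scheme.co2_affinity_factor * factor)
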