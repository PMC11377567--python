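"""AFM force-curve analysis: contact point, Hertz fit, indentation depth.

An approach force-distance curve (piezo position in nm, force in pN) is
analysed in three steps: (1) the contact point is located where the force
permanently rises above the pre-contact baseline; (2) the post-contact
segment is fitted to the Hertz contact model for the chosen tip geometry,
with the contact point refined jointly with the Young's modulus; (3) the
fitted model is inverted to report the indentation depth at a stated force
(500 pN for the original acquisitions).

Tip models (delta = indentation, E = Young's modulus in Pa, nu = Poisson
ratio):

* four-sided pyramid, half-angle alpha:  F = 0.7453 * E/(1-nu^2) * tan(alpha) * delta^2
* sphere, radius R:                      F = (4/3) * E/(1-nu^2) * sqrt(R) * delta^(3/2)

Indentation is the piezo travel past contact corrected for cantilever
deflection: delta = (z0 - z) - F/k, with k the spring constant.

Units: distances nm, forces pN, moduli Pa (1 Pa = 1e-6 pN/nm^2), spring
constants N/m (1 N/m = 1000 pN/nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DomainError, FitError, InvariantError, NoContactError

__all__ = [
    "TipModel",
    "ForceCurve",
    "HertzFit",
    "find_contact_point",
    "fit_hertz",
    "indentation_at_force",
    "hertz_force",
]

PA_TO_PN_PER_NM2 = 1e-6  # 1 Pa = 1e-6 pN/nm^2
N_PER_M_TO_PN_PER_NM = 1e3  # 1 N/m = 1000 pN/nm
BILODEAU = 0.7453  # four-sided pyramid prefactor


@dataclass(frozen=True)
class TipModel:
    """Indenter geometry: ``kind`` is ``"pyramid"`` (parameter = half-angle
    in degrees) or ``"sphere"`` (parameter = tip radius in nm)."""

    kind: str = "pyramid"
    parameter: float = 35.0

    def __post_init__(self) -> None:
        if self.kind not in ("pyramid", "sphere"):
            raise DomainError(f"unknown tip model {self.kind!r}")
        if self.parameter <= 0:
            raise DomainError("tip parameter must be positive")

    @property
    def exponent(self) -> float:
        return 2.0 if self.kind == "pyramid" else 1.5

    def prefactor(self, e_pa: float, nu: float) -> float:
        """Hertz prefactor C such that F[pN] = C * delta[nm]^exponent."""
        e = e_pa * PA_TO_PN_PER_NM2
        if self.kind == "pyramid":
            return BILODEAU * e / (1 - nu**2) * np.tan(np.radians(self.parameter))
        return (4.0 / 3.0) * e / (1 - nu**2) * np.sqrt(self.parameter)


def hertz_force(delta_nm, e_pa: float, nu: float, tip: TipModel) -> np.ndarray:
    """Hertz force (pN) at indentation depth(s) delta (nm)."""
    delta = np.clip(np.asarray(delta_nm, float), 0, None)
    return tip.prefactor(e_pa, nu) * delta**tip.exponent


@dataclass
class ForceCurve:
    """One approach force-distance curve.

    ``distance_nm`` is the nominal tip-sample separation (piezo axis),
    strictly monotone; ``force_pn`` the cantilever force.  ``spring_constant``
    in N/m is needed to correct indentation for cantilever deflection.
    """

    distance_nm: np.ndarray
    force_pn: np.ndarray
    spring_constant: float = 0.02
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.distance_nm = np.asarray(self.distance_nm, float)
        self.force_pn = np.asarray(self.force_pn, float)
        if self.distance_nm.shape != self.force_pn.shape:
            raise InvariantError("distance and force arrays differ in length")
        if self.distance_nm.size < 20:
            raise InvariantError("a force curve needs at least 20 samples")
        d = np.diff(self.distance_nm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvariantError("distances must be strictly monotone")
        if not np.all(np.isfinite(self.force_pn)):
            raise InvariantError("forces must be finite")

    def approach_order(self) -> tuple[np.ndarray, np.ndarray]:
        """Samples ordered from far (large separation) to near."""
        if self.distance_nm[0] >= self.distance_nm[-1]:
            return self.distance_nm, self.force_pn
        return self.distance_nm[::-1], self.force_pn[::-1]

    @property
    def k_pn_per_nm(self) -> float:
        return self.spring_constant * N_PER_M_TO_PN_PER_NM


@dataclass
class HertzFit:
    youngs_modulus_pa: float
    contact_point_nm: float
    tip: TipModel
    poisson_ratio: float
    residual_rms_pn: float
    n_fit_samples: int

    def __post_init__(self) -> None:
        if self.youngs_modulus_pa <= 0:
            raise FitError("fitted Young's modulus must be positive")


def find_contact_point(
    curve: ForceCurve, baseline_fraction: float = 0.3, k_sigma: float = 3.0
) -> float:
    """Locate the tip-sample contact point from the force baseline.

    The baseline level is estimated from the first ``baseline_fraction`` of
    approach samples as median + ``k_sigma`` robust standard deviations
    (1.4826 * MAD), so samples past contact that leak into the window do
    not inflate the level; the contact point is the separation of the last
    sample before the force permanently exceeds that level.  On soft
    samples this threshold estimate is systematically late (the force grows
    quadratically from contact); :func:`fit_hertz` refines it.
    """
    if not 0 < baseline_fraction < 0.9:
        raise DomainError("baseline_fraction must be in (0, 0.9)")
    z, f = curve.approach_order()
    n0 = max(2, int(len(f) * baseline_fraction))
    base = f[:n0]
    level = float(np.median(base) + k_sigma * 1.4826 * np.median(np.abs(base - np.median(base))))
    above = f > level
    if not above.any():
        raise NoContactError("force never exceeds the baseline level")
    # last index at/below the level after which force stays above
    below_idx = np.nonzero(~above)[0]
    if below_idx.size == 0:
        raise NoContactError("no pre-contact baseline found")
    last_below = below_idx[-1]
    if last_below == len(f) - 1:
        raise NoContactError("force does not remain above baseline")
    return float(z[last_below])


def _linear_e_fit(
    z: np.ndarray, f: np.ndarray, z0: float, curve: ForceCurve, tip: TipModel, nu: float
) -> tuple[float, float, int]:
    """Closed-form least-squares E for fixed z0; returns (E_pa, sse, n)."""
    delta = (z0 - z) - f / curve.k_pn_per_nm
    sel = delta > 0
    if sel.sum() < 3:
        return np.nan, np.inf, int(sel.sum())
    d = delta[sel] ** tip.exponent
    unit = tip.prefactor(1.0, nu)  # prefactor per Pa
    g = unit * d
    e = float((f[sel] @ g) / (g @ g))
    resid = f[sel] - e * g
    return e, float(resid @ resid), int(sel.sum())


def fit_hertz(
    curve: ForceCurve,
    tip: TipModel | None = None,
    nu: float = 0.5,
    max_force_pn: float = 500.0,
    baseline_fraction: float = 0.3,
) -> HertzFit:
    """Fit the Hertz model to the post-contact segment of an approach curve.

    The contact point from :func:`find_contact_point` seeds a joint
    refinement: for each candidate contact point the modulus has a
    closed-form least-squares solution, and the contact point minimising
    the residual is found by bounded scalar optimisation.  The fit window
    runs from contact up to ``max_force_pn`` (500 pN in the original
    protocol).
    """
    tip = tip or TipModel()
    if not 0 <= nu <= 0.5:
        raise DomainError("Poisson ratio must lie in [0, 0.5]")
    z, f = curve.approach_order()
    z0_init = find_contact_point(curve, baseline_fraction)
    window = f <= max_force_pn
    zw, fw = z[window], f[window]
    if (fw > 0).sum() < 10 or zw.size < 10:
        raise FitError("fewer than 10 post-contact samples in the fit window")

    spacing = float(np.abs(np.median(np.diff(z))))

    def objective(z0: float) -> float:
        _, sse, _ = _linear_e_fit(zw, fw, z0, curve, tip, nu)
        return sse

    # the threshold estimate lags true contact on soft samples, so scan an
    # asymmetric window (further towards earlier contact), then polish
    lo, hi = z0_init - 10 * spacing, z0_init + 40 * spacing
    grid = np.linspace(lo, hi, 101)
    best = float(grid[int(np.argmin([objective(g) for g in grid]))])
    step = (hi - lo) / 100
    res = minimize_scalar(
        objective, bounds=(best - step, best + step), method="bounded",
        options={"xatol": spacing * 1e-8},
    )
    z0 = float(res.x) if res.success and objective(float(res.x)) <= objective(best) else best
    if objective(z0) > objective(z0_init):
        z0 = z0_init
    e, sse, n = _linear_e_fit(zw, fw, z0, curve, tip, nu)
    if not np.isfinite(e):
        raise FitError("Hertz fit did not converge")
    if e <= 0:
        raise FitError(f"fit produced non-positive modulus {e:.3g} Pa")
    return HertzFit(
        youngs_modulus_pa=e,
        contact_point_nm=z0,
        tip=tip,
        poisson_ratio=nu,
        residual_rms_pn=float(np.sqrt(sse / n)),
        n_fit_samples=n,
    )


def indentation_at_force(fit: HertzFit, force_pn: float = 500.0) -> float:
    """Indentation depth (nm) at a stated applied force, from the fitted model.

    Inverts the tip model: pyramid ``delta = sqrt(F / C)``, sphere
    ``delta = (F / C)^(2/3)`` with C the fitted Hertz prefactor.
    """
    if force_pn <= 0:
        raise DomainError("force must be positive")
    c = fit.tip.prefactor(fit.youngs_modulus_pa, fit.poisson_ratio)
    return float((force_pn / c) ** (1.0 / fit.tip.exponent))
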