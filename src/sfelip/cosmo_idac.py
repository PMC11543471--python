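"""COSMO-SAC infinite-dilution activity coefficients in CO2-ethanol mixtures.

Solubility of a lipid in the supercritical CO2 + ethanol solvent phase is
characterised here by its infinite-dilution activity coefficient (IDAC,
gamma_inf): the non-ideality of the solute at vanishing mole fraction, with
low gamma_inf signalling strong solvent-solute affinity.  It is computed from
sigma profiles (discretised COSMO surface-screening-charge histograms) with
the standard segment-activity-coefficient (COSMO-SAC) functional form:

* an exchange energy per segment pair combining an electrostatic *misfit*
  term proportional to (sigma_m + sigma_n)^2 and a *hydrogen-bonding* term
  active only for strongly polar, opposite-sign pairs;
* self-consistent segment activity coefficients Gamma(sigma), solved by
  damped successive substitution;
* a Staverman-Guggenheim combinatorial term for size/shape effects, from the
  COSMO cavity area and volume.

Universal model parameters default to the published literature values and sit
in one config block (:class:`CosmoParameters`).  Pressure does not enter the
model; only temperature and composition do.  Correctness is asserted through
thermodynamic identities (pure-component limit, Gibbs-Duhem) rather than by
matching any external solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_core import ExtractionCondition, SigmaProfile, ValidationError, default_sigma_grid

__all__ = [
    "GAS_CONSTANT_KCAL",
    "CosmoParameters",
    "MixtureState",
    "SegmentGamma",
    "SolverError",
    "average_segments",
    "celsius_to_kelvin",
    "exchange_energy",
    "solve_segment_gammas",
    "ln_activity_coefficient",
    "idac_curve",
    "idac_for_condition",
    "flows_to_mole_fractions",
]

#: Gas constant in kcal/(mol K) — exchange energies are in kcal/mol.
GAS_CONSTANT_KCAL = 1.987204259e-3


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + 273.15


@dataclass(frozen=True)
class CosmoParameters:
    """Universal COSMO-SAC parameters (literature values).

    Attributes
    ----------
    a_eff : float
        Effective segment surface area, A^2.
    alpha_prime : float
        Misfit (electrostatic) energy constant, kcal A^4 / (mol e^2).
    c_hb : float
        Hydrogen-bonding energy constant, kcal A^4 / (mol e^2).
    sigma_hb : float
        Hydrogen-bonding cutoff charge density, e/A^2.
    q0, r0 : float
        Normalisation area (A^2) and volume (A^3) for the
        Staverman-Guggenheim combinatorial term.
    z : float
        Lattice coordination number.
    r_av : float
        Averaging radius for raw-segment charge smoothing, A.
    split_hb_profiles : bool
        Hook for a variant that splits sigma profiles into hydrogen-bonding
        and non-bonding parts before the segment solve; the default single-
        profile treatment applies the HB term inside the exchange energy.
    """

    a_eff: float = 7.50
    alpha_prime: float = 16466.72
    c_hb: float = 85580.0
    sigma_hb: float = 0.0084
    q0: float = 79.53
    r0: float = 66.69
    z: float = 10.0
    r_av: float = 0.81764
    split_hb_profiles: bool = False

    def __post_init__(self) -> None:
        if self.split_hb_profiles:
            raise NotImplementedError(
                "split hydrogen-bond sigma profiles are a documented hook, "
                "not implemented; use the single-profile HB term"
            )


DEFAULT_PARAMETERS = CosmoParameters()


@dataclass
class MixtureState:
    """Components, mole fractions and temperature of one liquid mixture."""

    components: list[SigmaProfile]
    x: np.ndarray
    T: float  # Kelvin

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if len(self.components) != self.x.size:
            raise ValidationError("mole fractions do not match components")
        if np.any(self.x < 0):
            raise ValidationError("negative mole fraction")
        if abs(self.x.sum() - 1.0) > 1e-12:
            raise ValidationError(f"mole fractions sum to {self.x.sum()!r}, not 1")
        if self.T <= 0:
            raise ValidationError("temperature must be positive (Kelvin)")


@dataclass
class SegmentGamma:
    """Converged segment activity coefficients ln Gamma(sigma) on a grid."""

    grid: np.ndarray
    ln_gamma: np.ndarray
    residual: float
    iterations: int


class SolverError(RuntimeError):
    """Raised when the segment self-consistency iteration fails to converge."""


# ---------------------------------------------------------------------------
# Raw-segment averaging (consumes COSMO-format surface segments)
# ---------------------------------------------------------------------------


def average_segments(
    raw_segments,
    r_av: float | None = None,
    grid: np.ndarray | None = None,
    name: str = "molecule",
    volume: float | None = None,
) -> SigmaProfile:
    """Spatially average raw surface-segment charge densities and bin them.

    ``raw_segments`` is a sequence of ``(position, area, sigma)`` with
    position a 3-vector (A), area in A^2 and sigma in e/A^2.  Each segment's
    density is replaced by a distance-weighted average over all segments with
    the standard radius-``r_av`` kernel

        w_mn = (r_n^2 r_av^2 / (r_n^2 + r_av^2)) exp(-d_mn^2 / (r_n^2 + r_av^2)),

    r_n^2 = a_n / pi, then its area is deposited on the sigma grid, linearly
    split between the two neighbouring bins so the first moment is preserved.
    Densities outside the grid are clipped with a warning.
    """
    params = DEFAULT_PARAMETERS
    if r_av is None:
        r_av = params.r_av
    if grid is None:
        grid = default_sigma_grid()
    segs = list(raw_segments)
    if not segs:
        raise ValidationError("empty segment list")
    pos = np.array([np.asarray(s[0], dtype=float) for s in segs])
    areas = np.array([float(s[1]) for s in segs])
    sig = np.array([float(s[2]) for s in segs])
    if np.any(areas <= 0):
        raise ValidationError("segment areas must be positive")

    rn2 = areas / np.pi
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    denom = rn2[None, :] + r_av**2
    w = (rn2[None, :] * r_av**2 / denom) * np.exp(-d2 / denom)
    sig_avg = (w * sig[None, :]).sum(axis=1) / w.sum(axis=1)

    lo, hi = grid[0], grid[-1]
    if np.any(sig_avg < lo) or np.any(sig_avg > hi):
        warnings.warn("averaged charge densities outside sigma grid were clipped")
        sig_avg = np.clip(sig_avg, lo, hi)

    step = grid[1] - grid[0]
    p = np.zeros_like(grid)
    idx = np.clip(((sig_avg - lo) / step).astype(int), 0, len(grid) - 2)
    frac = (sig_avg - grid[idx]) / step
    np.add.at(p, idx, areas * (1.0 - frac))
    np.add.at(p, idx + 1, areas * frac)

    total_area = float(areas.sum())
    vol = volume if volume is not None else total_area  # placeholder when unknown
    return SigmaProfile(name=name, area=total_area, volume=vol, grid=grid, p=p)


# ---------------------------------------------------------------------------
# Exchange energy and segment self-consistency
# ---------------------------------------------------------------------------


def exchange_energy(
    sigma_m, sigma_n, T: float | None = None, params: CosmoParameters = DEFAULT_PARAMETERS
):
    """Segment-pair exchange energy Delta W in kcal/mol.

    Misfit term (alpha'/2)(sigma_m+sigma_n)^2 plus hydrogen-bonding term
    c_hb * max(0, sigma_acc - sigma_hb) * min(0, sigma_don + sigma_hb), which
    is non-zero only when one segment is strongly positive and the other
    strongly negative (beyond the cutoff).  Symmetric in its arguments;
    temperature-independent in this parameterisation (``T`` accepted for
    interface uniformity).
    """
    sm = np.asarray(sigma_m, dtype=float)
    sn = np.asarray(sigma_n, dtype=float)
    misfit = 0.5 * params.alpha_prime * (sm + sn) ** 2
    acc = np.maximum(sm, sn)
    don = np.minimum(sm, sn)
    hb = params.c_hb * np.maximum(0.0, acc - params.sigma_hb) * np.minimum(0.0, don + params.sigma_hb)
    return misfit + hb


def _psi_matrix(grid: np.ndarray, T: float, params: CosmoParameters) -> np.ndarray:
    dW = exchange_energy(grid[:, None], grid[None, :], T, params)
    return np.exp(-dW / (GAS_CONSTANT_KCAL * T))


def solve_segment_gammas(
    p_normalized: np.ndarray,
    T: float,
    grid: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 5000,
    damping: float = 0.5,
    params: CosmoParameters = DEFAULT_PARAMETERS,
    psi: np.ndarray | None = None,
) -> SegmentGamma:
    """Solve the segment self-consistency equation

        ln Gamma(sigma_m) = -ln( sum_n p(sigma_n) Gamma(sigma_n)
                                  exp(-DeltaW(sigma_m, sigma_n) / RT) )

    by successive substitution, mixing old and new iterates in log space with
    factor ``damping`` (1 = undamped; the 0.5 default tames the oscillation
    the hydrogen-bond term induces).  ``p_normalized`` must sum to 1.

    Raises :class:`SolverError` (carrying the last residual) on
    non-convergence.
    """
    if grid is None:
        grid = default_sigma_grid()
    p = np.asarray(p_normalized, dtype=float)
    if p.shape != grid.shape:
        raise ValidationError("profile and grid shapes differ")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError(f"mixture sigma profile not normalized (sum={p.sum()!r})")
    if not (0.0 < damping <= 1.0):
        raise ValidationError("damping must be in (0, 1]")
    if psi is None:
        psi = _psi_matrix(grid, T, params)
    ln_g = np.zeros_like(grid)
    residual = np.inf
    for it in range(1, max_iter + 1):
        ln_new = -np.log(psi @ (p * np.exp(ln_g)))
        residual = float(np.max(np.abs(ln_new - ln_g)))
        ln_g = (1.0 - damping) * ln_g + damping * ln_new
        if residual <= tol:
            return SegmentGamma(grid=grid, ln_gamma=ln_g, residual=residual, iterations=it)
    raise SolverError(
        f"segment gammas did not converge in {max_iter} iterations "
        f"(last residual {residual:.3e})"
    )


# ---------------------------------------------------------------------------
# Activity coefficient of a component in a mixture
# ---------------------------------------------------------------------------


def _staverman_guggenheim(i: int, state: MixtureState, params: CosmoParameters) -> float:
    r = np.array([c.volume for c in state.components]) / params.r0
    q = np.array([c.area for c in state.components]) / params.q0
    x = state.x
    phi_over_x = r / float(x @ r)
    theta_over_x = q / float(x @ q)
    ell = 0.5 * params.z * (r - q) - (r - 1.0)
    return float(
        np.log(phi_over_x[i])
        + 0.5 * params.z * q[i] * np.log(theta_over_x[i] / phi_over_x[i])
        + ell[i]
        - phi_over_x[i] * float(x @ ell)
    )


def ln_activity_coefficient(
    component_index: int,
    state: MixtureState,
    params: CosmoParameters = DEFAULT_PARAMETERS,
    tol: float = 1e-12,
    max_iter: int = 5000,
    _psi: np.ndarray | None = None,
) -> float:
    """ln gamma of one component in a mixture: residual (segment) part plus
    Staverman-Guggenheim combinatorial part.

    The residual part is A_i / a_eff * sum_sigma p_i(sigma) [ln Gamma_mix -
    ln Gamma_pure](sigma) with p_i the component's normalised profile.
    Exactly zero (to solver tolerance) for a pure component.
    """
    comp = state.components[component_index]
    grid = comp.grid
    for other in state.components:
        if other.grid.shape != grid.shape or not np.allclose(other.grid, grid):
            raise ValidationError("all sigma profiles must share one grid")
    psi = _psi_matrix(grid, state.T, params) if _psi is None else _psi
    areas = np.array([c.area for c in state.components])
    xA = state.x * areas
    p_mix = np.sum([xa * c.normalized() for xa, c in zip(xA, state.components)], axis=0) / xA.sum()
    g_mix = solve_segment_gammas(p_mix, state.T, grid, tol, max_iter, params=params, psi=psi)
    g_pure = solve_segment_gammas(
        comp.normalized(), state.T, grid, tol, max_iter, params=params, psi=psi
    )
    residual_part = float(
        (comp.p / params.a_eff) @ (g_mix.ln_gamma - g_pure.ln_gamma)
    )
    return residual_part + _staverman_guggenheim(component_index, state, params)


# ---------------------------------------------------------------------------
# IDAC curves over ethanol composition, and the flow -> composition map
# ---------------------------------------------------------------------------


def idac_curve(
    lipid_profile: SigmaProfile,
    solvent_profiles: tuple[SigmaProfile, SigmaProfile],
    T: float,
    x_ethanol_grid,
    x_lipid: float = 1e-5,
    params: CosmoParameters = DEFAULT_PARAMETERS,
) -> np.ndarray:
    """ln gamma_inf of the lipid across an ethanol-fraction grid.

    ``solvent_profiles`` is (CO2, ethanol).  At each grid point the solvent
    mole fractions are scaled to (1 - x_lipid) and the lipid is pinned at
    ``x_lipid`` (default 1e-5, effectively infinite dilution).  ``T`` in
    Kelvin.
    """
    xg = np.asarray(x_ethanol_grid, dtype=float)
    if np.any((xg < 0) | (xg >= 1)):
        raise ValidationError("x_ethanol grid values must lie in [0, 1)")
    co2, ethanol = solvent_profiles
    psi = _psi_matrix(lipid_profile.grid, T, params)
    out = np.empty(xg.size)
    for k, xe in enumerate(xg):
        x = np.array([(1.0 - xe) * (1.0 - x_lipid), xe * (1.0 - x_lipid), x_lipid])
        state = MixtureState(components=[co2, ethanol, lipid_profile], x=x, T=T)
        out[k] = ln_activity_coefficient(2, state, params, _psi=psi)
    return out


def flows_to_mole_fractions(
    condition: ExtractionCondition,
    rho_ethanol: float = 0.789,
    rho_co2: float = 0.90,
    M_ethanol: float = 46.07,
    M_co2: float = 44.01,
) -> tuple[float, float]:
    """(x_CO2, x_ethanol) of the solvent feed from volumetric pump flows.

    Molar flow of each solvent is Q * rho / M with pump-side liquid densities
    (g/mL) and molar masses (g/mol); the defaults are ethanol at ambient
    conditions and liquid CO2 at pump head.
    """
    if condition.co2_flow <= 0:
        raise ValidationError("non-positive CO2 flow")
    if condition.ethanol_flow < 0:
        raise ValidationError("negative ethanol flow")
    n_eth = condition.ethanol_flow * rho_ethanol / M_ethanol
    n_co2 = condition.co2_flow * rho_co2 / M_co2
    total = n_eth + n_co2
    return n_co2 / total, n_eth / total


def idac_for_condition(
    lipid_profile: SigmaProfile,
    co2_profile: SigmaProfile,
    ethanol_profile: SigmaProfile,
    condition: ExtractionCondition,
    x_lipid: float = 1e-5,
    params: CosmoParameters = DEFAULT_PARAMETERS,
) -> float:
    """ln gamma_inf of a lipid at one extraction condition (temperature and
    feed ethanol fraction; pressure does not enter the model)."""
    _, x_eth = flows_to_mole_fractions(condition)
    T = celsius_to_kelvin(condition.temperature)
    return float(
        idac_curve(lipid_profile, (co2_profile, ethanol_profile), T, [x_eth], x_lipid, params)[0]
    )
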