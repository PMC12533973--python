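"""Unsteady lumped-resistance network hemodynamics with tuned outlet resistances.

The 3D pulsatile flow problem is reduced to a resistive vascular network:
each segment carries a linear Poiseuille resistance obtained by integrating
``8 mu / (pi r(s)^4)`` along its radius profile, and stenosed segments add a
Young–Tsai-type quadratic loss ``K_t rho (A_ref/A_throat - 1)^2 Q|Q| /
(2 A_ref^2)`` that captures the convective losses dominating severe
constrictions.  Outlets close with lumped resistances to a zero reference
pressure.  A prescribed pulsatile inlet flow (cardiac cycle 0.83 s, cardiac
output 79 mL/s by default) drives the network; at every time step nodal mass
conservation is solved for the instantaneous pressure field, so flows are
quasi-steady within the cycle.

Outlet resistances are estimated from total arterial resistance
``TAR = MAP / CO`` and tuned iteratively (multiplicative update on each
outlet, global rescale to hold the mean arterial pressure) until every outlet
carries its target fraction of cardiac output: 65% of CO to the descending
aorta, configured cerebral fractions for the six brain outlets, and the
residual split between external carotids and subclavians in proportion to
their cross-sectional areas.  Once tuned on the no-stenosis baseline, the
resistances are held fixed across all stenosis models so that differences in
flow routing arise from the stenoses alone.

Units: mmHg, mL/s, mm, s at the interface; conversions are centralized here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .vasculature import CEREBRAL_OUTLETS, ConfigurationError, NetworkTopology

__all__ = [
    "MMHG_TO_G_MM_S2",
    "FluidProperties",
    "CardiacWaveform",
    "FlowTargets",
    "OutletResistanceSet",
    "FlowSolution",
    "mean_arterial_pressure",
    "total_arterial_resistance",
    "target_flow_splits",
    "tune_outlet_resistances",
    "solve_unsteady",
    "steady_solve",
    "segment_velocity_field",
    "cross_section_flux",
    "cycle_average_flux",
    "communicator_flow_map",
]

#: 1 mmHg in g / (mm s^2)  (= Pa, since 1 Pa = 1 g / (mm s^2)).
MMHG_TO_G_MM_S2 = 133.322
#: Linear resistance conversion: g/(mm^4 s)  ->  mmHg s / mL.
_RLIN_TO_MMHG = 1.0e3 / MMHG_TO_G_MM_S2
#: Quadratic coefficient conversion: g/mm^7  ->  mmHg s^2 / mL^2.
_KQUAD_TO_MMHG = 1.0e6 / MMHG_TO_G_MM_S2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as an incompressible Newtonian fluid."""

    viscosity_cp: float = 4.0  # cP
    density_g_cc: float = 1.06  # g/cc

    def __post_init__(self) -> None:
        if self.viscosity_cp <= 0 or self.density_g_cc <= 0:
            raise ValueError("viscosity and density must be positive")

    @property
    def mu(self) -> float:
        """Dynamic viscosity in g/(mm s)."""
        return self.viscosity_cp * 1.0e-3

    @property
    def rho(self) -> float:
        """Density in g/mm^3."""
        return self.density_g_cc * 1.0e-3


@dataclass(frozen=True)
class CardiacWaveform:
    """Periodic aortic inflow pulse with prescribed period and mean flow.

    The default shape is a smooth systolic sin^2 bump over a systolic fraction
    of the cycle on top of a small diastolic baseline flow; the cycle average
    equals ``mean_flow`` exactly.  Any other shape can be supplied as a
    normalized callable f(phase) of cycle phase in [0, 1).
    """

    period: float = 0.83  # s
    mean_flow: float = 79.0  # mL/s (cardiac output)
    systolic_fraction: float = 0.35
    diastolic_level: float = 0.04
    shape: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def _raw(self, phase: np.ndarray) -> np.ndarray:
        if self.shape is not None:
            return np.asarray(self.shape(phase), dtype=float)
        phase = np.asarray(phase, dtype=float)
        sf, d = self.systolic_fraction, self.diastolic_level
        bump = np.where(phase < sf, np.sin(np.pi * phase / sf) ** 2, 0.0)
        return bump + d

    def _raw_mean(self) -> float:
        if self.shape is None:
            return 0.5 * self.systolic_fraction + self.diastolic_level
        ph = np.linspace(0.0, 1.0, 20001, endpoint=False)
        return float(np.mean(self._raw(ph)))

    def flow(self, t: np.ndarray) -> np.ndarray:
        """Inlet flow Q(t) in mL/s; periodic with the cardiac period."""
        phase = np.mod(np.asarray(t, dtype=float) / self.period, 1.0)
        return self.mean_flow * self._raw(phase) / self._raw_mean()

    def dflow(self, t: np.ndarray) -> np.ndarray:
        """dQ/dt in mL/s^2 (central difference on the periodic pulse)."""
        h = 1.0e-5 * self.period
        return (self.flow(np.asarray(t) + h) - self.flow(np.asarray(t) - h)) / (2 * h)


@dataclass
class FlowTargets:
    """Target outlet flow fractions (summing to 1) and the tuning pressure."""

    fractions: Dict[str, float]
    map_mmhg: float = 93.33
    tolerance: float = 0.01

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1.0e-9:
            raise ConfigurationError(f"outlet fractions sum to {total}, expected 1")


@dataclass
class OutletResistanceSet:
    """Lumped outlet resistances, mmHg s / mL, reusable across stenosis models."""

    resistances: Dict[str, float]
    iterations: int = 0
    log: List[Dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, r in self.resistances.items():
            if not np.isfinite(r) or r <= 0:
                raise ConfigurationError(f"outlet {label}: resistance must be finite > 0")


@dataclass
class FlowSolution:
    """One periodic cycle of network flow: per-segment Q(t), per-node P(t).

    Flows are signed, positive from proximal to distal node, in mL/s;
    pressures in mmHg.  ``times`` spans one period starting at 0.
    """

    network: NetworkTopology
    times: np.ndarray  # (n_t,)
    period: float
    segment_flow: Dict[str, np.ndarray]  # sid -> (n_t,) mL/s
    node_pressure: Dict[str, np.ndarray]  # node -> (n_t,) mmHg
    outlet_flow: Dict[str, np.ndarray]  # outlet label -> (n_t,) mL/s
    mass_residual: float = 0.0  # max interior-node imbalance, mL/s

    def cycle_mean(self, sid: str) -> float:
        return float(np.mean(self.segment_flow[sid]))

    def outlet_cycle_means(self) -> Dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.outlet_flow.items()}


# ---------------------------------------------------------------------------
# Scalar formulas
# ---------------------------------------------------------------------------

def mean_arterial_pressure(systolic: float, diastolic: float) -> float:
    """MAP = diastolic + (systolic - diastolic)/3, mmHg."""
    if diastolic <= 0:
        raise ValueError("diastolic pressure must be positive")
    if systolic < diastolic:
        raise ValueError("systolic pressure below diastolic")
    return diastolic + (systolic - diastolic) / 3.0


def total_arterial_resistance(map_mmhg: float, co_ml_s: float) -> float:
    """TAR = MAP / CO, mmHg s / mL."""
    if map_mmhg <= 0 or co_ml_s <= 0:
        raise ValueError("MAP and CO must be positive")
    return map_mmhg / co_ml_s


# ---------------------------------------------------------------------------
# Targets and tuning
# ---------------------------------------------------------------------------

#: Default cerebral outlet fractions of cardiac output.  The six fractions
#: follow the physiologic MCA > ACA >= PCA territory ordering and total 15%
#: of CO (a typical total cerebral blood flow); they are config-replaceable.
DEFAULT_CEREBRAL_FRACTIONS: Dict[str, float] = {
    "l_mca": 0.0375,
    "r_mca": 0.0375,
    "l_aca": 0.0200,
    "r_aca": 0.0200,
    "l_pca": 0.0175,
    "r_pca": 0.0175,
}


def target_flow_splits(network: NetworkTopology, config: Optional[dict] = None) -> FlowTargets:
    """Assemble the target outlet flow division.

    The descending aorta receives its configured fraction of CO (default
    0.65); the six cerebral outlets receive configured fractions; the residual
    is split across external carotids and subclavians in proportion to their
    outlet cross-sectional areas.
    """
    cfg = config or {}
    desc = float(cfg.get("descending_aorta_fraction", 0.65))
    cerebral = dict(cfg.get("cerebral_fractions", DEFAULT_CEREBRAL_FRACTIONS))
    missing = [o for o in CEREBRAL_OUTLETS if o not in cerebral]
    if missing:
        raise ConfigurationError(f"missing cerebral fractions for {missing}")
    fixed = desc + sum(cerebral.values())
    if fixed >= 1.0:
        raise ConfigurationError(f"configured fractions total {fixed} >= 1")
    residual_outlets = [
        o for o in network.outlets
        if o != "descending_aorta" and o not in cerebral
    ]
    areas = {}
    for label in residual_outlets:
        node = network.outlets[label]
        seg = next(
            s for s in network.segments.values()
            if node in (s.proximal_node, s.distal_node)
        )
        r_out = seg.radii[-1] if seg.distal_node == node else seg.radii[0]
        areas[label] = np.pi * r_out**2
    total_area = sum(areas.values())
    fractions = {"descending_aorta": desc, **cerebral}
    for label, area in areas.items():
        fractions[label] = (1.0 - fixed) * area / total_area
    return FlowTargets(
        fractions=fractions,
        map_mmhg=float(cfg.get("map_mmhg", mean_arterial_pressure(120.0, 80.0))),
        tolerance=float(cfg.get("tolerance", 0.01)),
    )


# ---------------------------------------------------------------------------
# Network assembly and steady/unsteady solves
# ---------------------------------------------------------------------------

def _segment_coefficients(network: NetworkTopology, fluid: FluidProperties,
                          stenosis_k: float = 1.52):
    """Per-segment (R_lin, K_quad) in mmHg s/mL and mmHg s^2/mL^2.

    R_lin integrates the Poiseuille kernel along the radius profile; K_quad is
    the Young–Tsai-type convective loss for stenosed segments (zero elsewhere).
    Occluded segments are excluded entirely.
    """
    coeffs = {}
    for sid, seg in network.segments.items():
        if seg.occluded:
            continue
        s = seg.arclengths
        kernel = 8.0 * fluid.mu / (np.pi * seg.radii**4)
        r_lin = float(np.trapezoid(kernel, s)) * _RLIN_TO_MMHG
        k_quad = 0.0
        if seg.stenosis is not None and not seg.occluded:
            i_throat = int(np.argmin(seg.radii))
            r_throat = float(seg.radii[i_throat])
            # Reference radius: healthy lumen just proximal to the taper.
            sten = seg.stenosis
            r_ref = seg.radius_at(max(sten.s_start - 1.0, 0.0))
            a_ref = np.pi * r_ref**2
            a_throat = np.pi * r_throat**2
            k_quad = (
                stenosis_k * fluid.rho * (a_ref / a_throat - 1.0) ** 2
                / (2.0 * a_ref**2)
            ) * _KQUAD_TO_MMHG
        coeffs[sid] = (r_lin, k_quad)
    return coeffs


class _NetworkSystem:
    """Indexed arrays for repeated nodal solves of one network."""

    def __init__(self, network: NetworkTopology, fluid: FluidProperties,
                 resistances: OutletResistanceSet, stenosis_k: float = 1.52):
        self.network = network
        coeffs = _segment_coefficients(network, fluid, stenosis_k)
        self.sids = sorted(coeffs)
        nodes = sorted({n for sid in self.sids for n in
                        (network.segments[sid].proximal_node,
                         network.segments[sid].distal_node)})
        self.nodes = nodes
        self.n_idx = {n: i for i, n in enumerate(nodes)}
        self.prox = np.array([self.n_idx[network.segments[s].proximal_node] for s in self.sids])
        self.dist = np.array([self.n_idx[network.segments[s].distal_node] for s in self.sids])
        self.r_lin = np.array([coeffs[s][0] for s in self.sids])
        self.k_quad = np.array([coeffs[s][1] for s in self.sids])
        self.inlet = self.n_idx[network.inlet]
        self.outlet_labels = sorted(network.outlets)
        missing = [network.outlets[o] for o in self.outlet_labels
                   if network.outlets[o] not in self.n_idx]
        if missing:
            raise ConfigurationError(
                f"outlet node(s) disconnected from inlet: {missing}"
            )
        self.outlet_nodes = np.array(
            [self.n_idx[network.outlets[o]] for o in self.outlet_labels]
        )
        self.r_out = np.array([resistances.resistances[o] for o in self.outlet_labels])

    def solve(self, q_in: float, q_warm: Optional[np.ndarray] = None,
              tol: float = 1.0e-12, max_iter: int = 200):
        """Solve nodal conservation at one instant (nonlinear in stenosis flow).

        Returns (segment flows mL/s, node pressures mmHg, outlet flows mL/s,
        interior mass residual mL/s).
        """
        n = len(self.nodes)
        q = np.zeros(len(self.sids)) if q_warm is None else q_warm.copy()
        scale = max(abs(q_in), 1.0)
        p = np.zeros(n)
        for _ in range(max_iter):
            g = 1.0 / (self.r_lin + self.k_quad * np.abs(q))
            G = np.zeros((n, n))
            np.add.at(G, (self.prox, self.prox), g)
            np.add.at(G, (self.dist, self.dist), g)
            np.add.at(G, (self.prox, self.dist), -g)
            np.add.at(G, (self.dist, self.prox), -g)
            G[self.outlet_nodes, self.outlet_nodes] += 1.0 / self.r_out
            b = np.zeros(n)
            b[self.inlet] = q_in
            p = np.linalg.solve(G, b)
            q_new = g * (p[self.prox] - p[self.dist])
            if np.max(np.abs(q_new - q)) < tol * scale:
                q = q_new
                break
            q = q_new
        q_out = p[self.outlet_nodes] / self.r_out
        # Interior residual evaluated with the converged conductances.
        resid = np.zeros(n)
        np.add.at(resid, self.prox, -q)
        np.add.at(resid, self.dist, q)
        resid[self.outlet_nodes] -= q_out
        resid[self.inlet] += q_in
        return q, p, q_out, float(np.max(np.abs(resid)))


def steady_solve(network: NetworkTopology, q_in: float,
                 resistances: OutletResistanceSet, fluid: FluidProperties,
                 stenosis_k: float = 1.52):
    """One steady nodal solve at inlet flow ``q_in`` (mL/s).

    Returns (segment flows dict, node pressures dict, outlet flows dict).
    """
    sys = _NetworkSystem(network, fluid, resistances, stenosis_k)
    q, p, q_out, _ = sys.solve(q_in)
    return (
        dict(zip(sys.sids, q)),
        dict(zip(sys.nodes, p)),
        dict(zip(sys.outlet_labels, q_out)),
    )


def tune_outlet_resistances(
    network: NetworkTopology,
    targets: FlowTargets,
    waveform: CardiacWaveform,
    fluid: FluidProperties,
    tol: Optional[float] = None,
    max_iter: int = 200,
) -> OutletResistanceSet:
    """Iteratively tune outlet resistances to the target flow division.

    Repeated steady solves at the mean inlet flow adjust each resistance
    multiplicatively (``R_i <- R_i (Q_i / Q_target_i)``), with a global
    rescale holding the inlet pressure at MAP so the total network admittance
    stays consistent with TAR.  Raises on non-convergence, reporting the
    residuals.
    """
    tol = targets.tolerance if tol is None else tol
    co = waveform.mean_flow
    q_tgt = {o: targets.fractions[o] * co for o in targets.fractions}
    res = OutletResistanceSet(
        resistances={o: targets.map_mmhg / q for o, q in q_tgt.items()}
    )
    log: List[Dict[str, float]] = []
    for it in range(1, max_iter + 1):
        sys = _NetworkSystem(network, fluid, res)
        _, p, q_out, _ = sys.solve(co)
        q_map = dict(zip(sys.outlet_labels, q_out))
        p_in = p[sys.inlet]
        frac_err = max(abs(q_map[o] / q_tgt[o] - 1.0) for o in q_tgt)
        map_err = abs(p_in / targets.map_mmhg - 1.0)
        log.append({"iteration": it, "max_fraction_error": frac_err,
                    "map_error": map_err})
        if frac_err < tol and map_err < tol:
            return OutletResistanceSet(resistances=res.resistances,
                                       iterations=it, log=log)
        scale = targets.map_mmhg / p_in
        res = OutletResistanceSet(
            resistances={
                o: res.resistances[o] * (q_map[o] / q_tgt[o]) * scale
                for o in q_tgt
            }
        )
    raise RuntimeError(
        f"resistance tuning did not converge in {max_iter} iterations; "
        f"last residuals: {log[-1]}"
    )


def solve_unsteady(
    network: NetworkTopology,
    waveform: CardiacWaveform,
    resistances: OutletResistanceSet,
    fluid: FluidProperties,
    dt_flow: float = 1.0e-3,
    n_cycles: int = 3,
    stenosis_k: float = 1.52,
) -> FlowSolution:
    """Pulsatile network solve: nodal conservation at every step.

    The inlet flow follows the cardiac waveform; the network itself is
    quasi-steady (resistive), so the solve marches ``n_cycles`` cycles and
    returns the final one as the periodic solution.
    """
    sys = _NetworkSystem(network, fluid, resistances, stenosis_k)
    unreached = [n for n in network.outlets.values() if n not in sys.n_idx]
    if unreached:
        raise ConfigurationError(f"outlet node(s) disconnected from inlet: {unreached}")
    T = waveform.period
    n_t = int(round(T / dt_flow))
    times = np.arange(n_t) * dt_flow
    q_seg = np.zeros((len(sys.sids), n_t))
    p_node = np.zeros((len(sys.nodes), n_t))
    q_outlet = np.zeros((len(sys.outlet_nodes), n_t))
    warm = None
    max_resid = 0.0
    nonlinear = np.any(sys.k_quad > 0)
    for cycle in range(n_cycles):
        if cycle > 0 and not nonlinear:
            break  # purely linear network: cycles are identical by scaling
        for i, t in enumerate(times):
            q, p, q_out, resid = sys.solve(float(waveform.flow(t)), q_warm=warm)
            warm = q
            q_seg[:, i] = q
            p_node[:, i] = p
            q_outlet[:, i] = q_out
            max_resid = max(max_resid, resid)
    seg_flow = {sid: q_seg[k] for k, sid in enumerate(sys.sids)}
    for sid, seg in network.segments.items():
        if seg.occluded:
            seg_flow[sid] = np.zeros(n_t)
    return FlowSolution(
        network=network,
        times=times,
        period=T,
        segment_flow=seg_flow,
        node_pressure={nd: p_node[k] for k, nd in enumerate(sys.nodes)},
        outlet_flow={o: q_outlet[k] for k, o in enumerate(sys.outlet_labels)},
        mass_residual=max_resid,
    )


# ---------------------------------------------------------------------------
# Velocity reconstruction and flow integration
# ---------------------------------------------------------------------------

def segment_velocity_field(solution: FlowSolution, network: NetworkTopology,
                           fluid: FluidProperties):
    """Analytic in-segment velocity sampler for particle forcing.

    Inside each segment the axial velocity follows the quasi-steady Poiseuille
    profile ``2 Q(t) / (pi R(s)^2) (1 - (rho/R)^2)`` along the centerline
    tangent plus the first-order radial component required by mass
    conservation where ``R(s)`` varies; junction neighbourhoods blend adjacent
    segment fields.  Returns a :class:`embotrace.transport.VelocityField`.
    """
    from .transport import VelocityField

    return VelocityField.from_solution(solution, network, fluid)


def cross_section_flux(field, sid: str, s: float, t: float,
                       n_radial: int = 24, n_theta: int = 32) -> float:
    """Numerically integrate axial velocity over a cross-section (mL/s)."""
    c, t_hat, radius = field.section_frame(sid, s)
    e1 = np.cross(t_hat, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1.0e-6:
        e1 = np.cross(t_hat, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t_hat, e1)
    # Gauss-Legendre in rho^2 (exact for polynomial profiles), uniform theta.
    xg, wg = np.polynomial.legendre.leggauss(n_radial)
    u2 = 0.5 * (xg + 1.0)  # rho^2 / R^2 nodes
    w2 = 0.5 * wg
    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    flux = 0.0
    for u2_k, w_k in zip(u2, w2):
        rho = radius * np.sqrt(u2_k) * 0.999999
        ring = 0.0
        for th in thetas:
            x = c + rho * (np.cos(th) * e1 + np.sin(th) * e2)
            u = field.velocity(x, t, segment_hint=sid)
            ring += float(np.dot(u, t_hat))
        flux += w_k * (ring / n_theta)
    # integral = R^2 * pi * mean over (rho^2/R^2, theta); mm^3/s -> mL/s
    return flux * np.pi * radius**2 * 1.0e-3


def cycle_average_flux(field, sid: str, s: float, n_time: int = 16) -> float:
    """Time average of the cross-sectional flux over one cardiac period."""
    ts = np.linspace(0.0, field.period, n_time, endpoint=False)
    return float(np.mean([cross_section_flux(field, sid, s, t) for t in ts]))


#: Sign conventions for the communicating-artery flow map, applied to the
#: proximal->distal signed segment flow:
#:   AcoA  positive = right -> left
#:   PcoA  positive = posterior -> anterior
#:   P1    positive = basilar -> posterior cerebral junction
_COMMUNICATOR_SIGNS = {
    "acoa": 1.0,
    "l_p1": 1.0,
    "r_p1": 1.0,
    "l_pcoa": -1.0,
    "r_pcoa": -1.0,
}


def communicator_flow_map(solution: FlowSolution, network: NetworkTopology) -> Dict[str, float]:
    """Signed cycle-mean flows (mL/min) in the CoW communicators and feeders.

    Also reports each cervical feeder's fraction of total cerebral blood flow
    (LICA + RICA + basilar).
    """
    out: Dict[str, float] = {}
    for sid, sign in _COMMUNICATOR_SIGNS.items():
        out[sid] = sign * solution.cycle_mean(sid) * 60.0 if sid in solution.segment_flow else 0.0
    for sid, key in (("l_internal_carotid", "lica"), ("r_internal_carotid", "rica"),
                     ("basilar", "ba")):
        out[key] = solution.cycle_mean(sid) * 60.0
    tcbf = out["lica"] + out["rica"] + out["ba"]
    for key in ("lica", "rica", "ba"):
        out[f"{key}_fraction_tcbf"] = out[key] / tcbf if tcbf else np.nan
    out["tcbf"] = tcbf
    return out
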