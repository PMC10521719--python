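"""Cell-free transcription-translation kinetics for chemostat circuits.

The reaction model, per unit cell, couples gene expression from
surface-immobilized DNA templates to a lumped tx-tl resource pool ``E``
(energy charge plus usable machinery, arbitrary units, delivered with
every flush).  For each template ``i`` with effective concentration
``G_i`` (nM) and promoter regulation factor ``f_i``:

    dM_i/dt  = k_tx * G_i * f_i * rho  -  delta_m * M_i          + exch
    dPd_i/dt = k_tl * M_i * rho        -  k_mat * Pd_i           + exch
    dP_i/dt  = k_mat * Pd_i                                      + exch
    dE/dt    = -rho * sum_i (c_tx * k_tx * G_i * f_i
                             + c_tl * k_tl * M_i)                + exch

with ``rho = E / (K_E + E)`` the resource saturation factor, ``M`` mRNA,
``Pd`` immature (dark) protein and ``P`` mature fluorescent protein.
``exch(X) = k_cell,X * (X_res - X_cell)`` is the species-specific
diffusive exchange with the reservoir.

Translation additionally deposits a slowly-clearing load species ``W``
(spent machinery: stalled/inactivated ribosomal complexes and truncated
products) that inhibits further translation,

    psi     = 1 / (1 + (W / K_W)^h_W)
    dW/dt   = w_yield * k_tl * M * rho * psi  + exch(W)

and multiplies the translation terms above.  ``W`` is large (protein
complex class), so it is cleared only by diffusive exchange — slowly in
long-channel cells.  This term carries the device's observed
high-template-density behavior: an early expression burst that the
exchange rate cannot sustain, leveling out to a lower steady state; at
the recommended low template densities the load stays far below ``K_W``
and the model reduces to plain resource-limited expression.  Repression
is an independent-site product over promoter operator sites,

    f = prod_s 1 / (1 + (TF_free / Kd_s)^(n_s)),

and inducers sequester their repressor at instantaneous equilibrium,
``TF_free = TF_total / (1 + (I / K_I)^h)``.

Transcription factors act through total protein (dark + mature): DNA
binding does not require the fluorophore to have matured.  mRNA decays in
both compartments (nucleases are everywhere); synthesis and resource
consumption occur only in the unit cell, where the templates are anchored.

Default rate constants are a calibrated, frozen parameter set (the
``"default"`` preset): no rate measurements exist for this device, so the
constants were fixed once such that constitutive expression at the lowest
default template density reaches steady state in 4-6 h across all five
connecting-channel lengths, and high template densities overshoot early
before settling, mirroring the device's characterization behavior.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .device import (
    UnitCellGeometry,
    Species,
    SURFACE_BOUND,
    diffusivity_from_mw,
    exchange_rate_pair,
)

__all__ = [
    "OperatorSite",
    "GeneTemplate",
    "InducerBinding",
    "KineticParams",
    "CircuitSpec",
    "CircuitModel",
    "ConstitutiveSteadyState",
    "FixedPoint",
    "regulation_factor",
    "free_repressor",
    "circuit_rhs",
    "steady_state_constitutive",
    "find_stable_states",
    "PARAM_PRESETS",
]

RESOURCE = "E"
WASTE = "W"

#: inducer equilibrium constants (nM) and cooperativities, effective values
K_ATC_NM = 50.0
K_IPTG_NM = 2000.0

MW_ATC_KDA = 0.47
MW_IPTG_KDA = 0.24
MW_ZF_MSCARLET_KDA = 40.0


@dataclass(frozen=True)
class OperatorSite:
    """One repressor binding site in a promoter: which TF, how tightly."""

    tf_id: str
    kd_nm: float
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if self.kd_nm <= 0:
            raise ValueError("Kd must be > 0")
        if self.hill_n < 1:
            raise ValueError("Hill coefficient must be >= 1")


@dataclass(frozen=True)
class GeneTemplate:
    """A surface-immobilized expressible template.

    ``g_nm`` is the effective solution-phase template concentration for an
    undiluted spot (scaled down by the spot's dsDNA surface fraction when
    a plate map is applied).  The template itself never exchanges.
    """

    id: str
    product: str
    operators: tuple[OperatorSite, ...] = ()
    g_nm: float = 1.0
    product_mw_kda: float = 27.0

    def __post_init__(self) -> None:
        if self.g_nm < 0:
            raise ValueError("template concentration must be >= 0")
        object.__setattr__(self, "operators", tuple(self.operators))

    def with_g(self, g_nm: float) -> "GeneTemplate":
        return replace(self, g_nm=g_nm)


@dataclass(frozen=True)
class InducerBinding:
    """Instantaneous-equilibrium sequestration of a repressor by an inducer."""

    tf_id: str
    inducer: str
    k_i_nm: float
    hill_h: float = 1.0

    def __post_init__(self) -> None:
        if self.k_i_nm <= 0:
            raise ValueError("inducer binding constant must be > 0")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the resource-limited tx-tl model.

    Units: 1/s for rates, nM for concentrations, arbitrary resource units
    for the E pool.  ``mrna_mw_kda`` is an effective hydrodynamic size for
    actively translated (polysome-loaded) mRNA, so mRNA exchanges slowly;
    ``resource_mw_kda`` places the lumped resource in the protein class,
    because the machinery components dominate its transport.
    """

    k_tx: float = 8.0e-3       # mRNA (nM) per template (nM) per s, saturated
    k_tl: float = 2.0e-2       # protein (nM) per mRNA (nM) per s, saturated
    delta_m: float = 5.0e-4    # mRNA decay, 1/s (~33 min lifetime)
    k_mat: float = 2.0e-4      # fluorophore maturation, 1/s (~83 min)
    K_E: float = 25.0          # resource half-saturation (a.u.)
    c_tx: float = 0.002        # resource units per nM mRNA synthesized
    c_tl: float = 0.01         # resource units per nM protein synthesized
    E_supply: float = 100.0    # resource delivered by a standard 1:1 flush
    w_yield: float = 1.0       # load deposited per nM protein synthesized
    K_W: float = 2000.0        # load inhibition constant (nM)
    hill_w: float = 2.0        # load inhibition cooperativity
    mrna_mw_kda: float = 2000.0
    resource_mw_kda: float = 1.0
    waste_mw_kda: float = 250.0

    def __post_init__(self) -> None:
        for name in ("k_tx", "k_tl", "delta_m", "k_mat", "K_E",
                     "c_tx", "c_tl", "E_supply", "K_W", "hill_w",
                     "mrna_mw_kda", "resource_mw_kda", "waste_mw_kda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.w_yield < 0:
            raise ValueError("w_yield must be >= 0")

    def rho(self, e_level: float | None = None) -> float:
        e = self.E_supply if e_level is None else e_level
        return e / (self.K_E + e)


#: named, frozen parameter sets
PARAM_PRESETS: dict[str, KineticParams] = {
    "default": KineticParams(),
    # resource consumption and load deposition switched off: expression
    # never loads the E pool, so the constitutive closed form is exact
    # (used as an oracle regime)
    "unlimited_resource": KineticParams(c_tx=1e-12, c_tl=1e-12, w_yield=0.0),
}


@dataclass
class CircuitSpec:
    """A gene circuit: templates, supplied species, regulatory wiring.

    ``supplied`` maps externally formulated species (purified TFs,
    inducers) to their molecular weight (kDa); they are delivered through
    the reservoir and neither produced nor consumed.  ``initial`` gives
    nonzero initial cell-compartment concentrations by species name.
    """

    name: str
    templates: list[GeneTemplate]
    supplied: dict[str, float] = field(default_factory=dict)
    inducer_bindings: list[InducerBinding] = field(default_factory=list)
    reporters: list[str] = field(default_factory=list)
    initial: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        products = [t.product for t in self.templates]
        if len(set(products)) != len(products):
            raise ValueError("each template must have a unique product species")
        ids = [t.id for t in self.templates]
        if len(set(ids)) != len(ids):
            raise ValueError("template ids must be unique")
        available = set(products) | set(self.supplied)
        for t in self.templates:
            for site in t.operators:
                if site.tf_id not in available:
                    raise ValueError(
                        f"operator TF {site.tf_id!r} on template {t.id!r} is "
                        f"neither produced nor supplied")
        for b in self.inducer_bindings:
            if b.inducer not in self.supplied:
                raise ValueError(f"inducer {b.inducer!r} is not a supplied species")

    def scaled(self, factors: Mapping[str, float]) -> "CircuitSpec":
        """Copy with template concentrations scaled by id (e.g. a spot's
        surface fraction)."""
        templates = [t.with_g(t.g_nm * factors.get(t.id, 1.0))
                     for t in self.templates]
        return replace(self, templates=templates)


def regulation_factor(template: GeneTemplate,
                      free_tf: Mapping[str, float]) -> float:
    """Promoter activity in [0, 1]: independent-site repression product.

    f = prod over operator sites of 1 / (1 + (TF_free / Kd)^hill_n);
    an empty operator list gives 1 (unregulated template).
    """
    f = 1.0
    for site in template.operators:
        if site.tf_id not in free_tf:
            raise KeyError(f"no free-TF level provided for {site.tf_id!r}")
        tf = free_tf[site.tf_id]
        if tf < 0:
            raise ValueError("free TF concentration must be >= 0")
        f *= 1.0 / (1.0 + (tf / site.kd_nm) ** site.hill_n)
    return f


def free_repressor(total_nm: float, inducer_nm: float,
                   k_i_nm: float, hill_h: float = 1.0) -> float:
    """Free repressor after instantaneous inducer sequestration:
    free = total / (1 + (I / K_I)^h)."""
    if total_nm < 0 or inducer_nm < 0:
        raise ValueError("concentrations must be >= 0")
    if k_i_nm <= 0:
        raise ValueError("K_I must be > 0")
    return total_nm / (1.0 + (inducer_nm / k_i_nm) ** hill_h)


# -- compiled vectorized model ----------------------------------------------


class CircuitModel:
    """A circuit compiled against geometry into a vectorized ODE right side.

    Simulates ``n_cells`` independent unit cells sharing one circuit
    topology but per-cell template concentrations and connecting-channel
    lengths.  Two modes:

    * two-compartment (``clamped_reservoir=False``): the state carries
      cell and reservoir blocks; reservoirs evolve by conjugate exchange
      (this is the incubation model used by the protocol engine);
    * clamped (``clamped_reservoir=True``): reservoir concentrations are
      held fixed, giving the continuous-chemostat idealization whose
      constitutive fixed point has a closed form.

    Species order: per template (mRNA, dark protein, mature protein),
    then the resource pool, then supplied species.
    """

    def __init__(self, circuit: CircuitSpec, params: KineticParams,
                 geometries: Sequence[UnitCellGeometry],
                 g_scale: np.ndarray | None = None,
                 clamped_reservoir: bool = False):
        self.circuit = circuit
        self.params = params
        self.geometries = list(geometries)
        self.n_cells = len(self.geometries)
        self.clamped = clamped_reservoir

        tpls = circuit.templates
        self.n_tpl = len(tpls)
        self.species: list[str] = []
        self.i_mrna = np.zeros(self.n_tpl, dtype=int)
        self.i_dark = np.zeros(self.n_tpl, dtype=int)
        self.i_prot = np.zeros(self.n_tpl, dtype=int)
        mws: list[float] = []
        for j, t in enumerate(tpls):
            self.i_mrna[j] = len(self.species)
            self.species.append(f"mRNA:{t.id}")
            mws.append(params.mrna_mw_kda)
            self.i_dark[j] = len(self.species)
            self.species.append(f"{t.product}:dark")
            mws.append(t.product_mw_kda)
            self.i_prot[j] = len(self.species)
            self.species.append(t.product)
            mws.append(t.product_mw_kda)
        self.i_res = len(self.species)
        self.species.append(RESOURCE)
        mws.append(params.resource_mw_kda)
        self.i_waste = len(self.species)
        self.species.append(WASTE)
        mws.append(params.waste_mw_kda)
        self.i_supplied: dict[str, int] = {}
        for name, mw in circuit.supplied.items():
            self.i_supplied[name] = len(self.species)
            self.species.append(name)
            mws.append(mw)
        self.n_sp = len(self.species)
        self.index = {s: i for i, s in enumerate(self.species)}

        # per-cell, per-species exchange rates
        self.k_cell = np.zeros((self.n_cells, self.n_sp))
        self.k_resv = np.zeros((self.n_cells, self.n_sp))
        for i, sp_name in enumerate(self.species):
            sp = Species(sp_name, molecular_weight_kda=mws[i])
            for c, geom in enumerate(self.geometries):
                kc, kr = exchange_rate_pair(geom, sp)
                self.k_cell[c, i] = kc
                self.k_resv[c, i] = kr

        # per-cell template concentrations
        g = np.array([t.g_nm for t in tpls])[None, :] * np.ones((self.n_cells, 1))
        if g_scale is not None:
            g = g * np.asarray(g_scale, dtype=float).reshape(self.n_cells,
                                                             self.n_tpl)
        self.g_nm = g

        # TF wiring: for each template, which state columns sum to each
        # operator's total TF, and the operator constants
        self._tf_sources: dict[str, list[int]] = {}
        for t in tpls:
            self._tf_sources[t.product] = [int(self.i_dark[tpls.index(t)]),
                                           int(self.i_prot[tpls.index(t)])]
        for name in circuit.supplied:
            self._tf_sources.setdefault(name, []).append(self.i_supplied[name])
        self._bindings = {b.tf_id: b for b in circuit.inducer_bindings}
        self._decay = np.zeros(self.n_sp)
        self._decay[self.i_mrna] = params.delta_m

    # -- state helpers -----------------------------------------------------

    @property
    def n_state(self) -> int:
        blocks = 1 if self.clamped else 2
        return blocks * self.n_cells * self.n_sp

    def initial_state(self, reservoir: Mapping[str, float] | None = None) -> np.ndarray:
        """State with circuit initial conditions in the cells and, for the
        two-compartment mode, the given composition in the reservoirs."""
        cell = np.zeros((self.n_cells, self.n_sp))
        for name, conc in self.circuit.initial.items():
            cell[:, self.index[name]] = conc
        if self.clamped:
            return cell.ravel()
        res = np.zeros((self.n_cells, self.n_sp))
        if reservoir:
            for name, conc in reservoir.items():
                if name in self.index:
                    res[:, self.index[name]] = conc
        return np.concatenate([cell.ravel(), res.ravel()])

    def split(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_cells * self.n_sp
        cell = y[:n].reshape(self.n_cells, self.n_sp)
        if self.clamped:
            return cell, self._res_fixed
        return cell, y[n:].reshape(self.n_cells, self.n_sp)

    def set_clamped_reservoir(self, reservoir: Mapping[str, float]) -> None:
        res = np.zeros((self.n_cells, self.n_sp))
        for name, conc in reservoir.items():
            if name in self.index:
                res[:, self.index[name]] = conc
        self._res_fixed = res

    # -- the right-hand side ------------------------------------------------

    def free_tf_matrix(self, cell: np.ndarray) -> dict[str, np.ndarray]:
        """Free (inducer-corrected) TF concentration per cell, per TF id."""
        free: dict[str, np.ndarray] = {}
        for tf_id, cols in self._tf_sources.items():
            total = np.clip(cell[:, cols].sum(axis=1), 0.0, None)
            b = self._bindings.get(tf_id)
            if b is not None:
                inducer = np.clip(cell[:, self.index[b.inducer]], 0.0, None)
                total = total / (1.0 + (inducer / b.k_i_nm) ** b.hill_h)
            free[tf_id] = total
        return free

    def regulation_matrix(self, cell: np.ndarray) -> np.ndarray:
        """(n_cells, n_templates) promoter activity factors."""
        free = self.free_tf_matrix(cell)
        f = np.ones((self.n_cells, self.n_tpl))
        for j, t in enumerate(self.circuit.templates):
            for site in t.operators:
                tf = free[site.tf_id]
                f[:, j] *= 1.0 / (1.0 + (tf / site.kd_nm) ** site.hill_n)
        return f

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        cell, res = self.split(y)
        exch_cell = self.k_cell * (res - cell)

        e = np.clip(cell[:, self.i_res], 0.0, None)
        rho = e / (p.K_E + e)
        w = np.clip(cell[:, self.i_waste], 0.0, None)
        psi = 1.0 / (1.0 + (w / p.K_W) ** p.hill_w)

        f = self.regulation_matrix(cell)
        tx = p.k_tx * self.g_nm * f                      # (n_cells, n_tpl)
        m = cell[:, self.i_mrna]
        tl = p.k_tl * np.clip(m, 0.0, None) * psi[:, None]

        d_cell = exch_cell.copy()
        d_cell[:, self.i_mrna] += tx * rho[:, None] - p.delta_m * m
        d_cell[:, self.i_dark] += (tl * rho[:, None]
                                   - p.k_mat * cell[:, self.i_dark])
        d_cell[:, self.i_prot] += p.k_mat * cell[:, self.i_dark]
        d_cell[:, self.i_res] -= rho * (p.c_tx * tx + p.c_tl * tl).sum(axis=1)
        d_cell[:, self.i_waste] += p.w_yield * rho * tl.sum(axis=1)

        if self.clamped:
            return d_cell.ravel()

        d_res = self.k_resv * (cell - res) - self._decay[None, :] * res
        return np.concatenate([d_cell.ravel(), d_res.ravel()])

    # -- integration --------------------------------------------------------

    def integrate(self, y0: np.ndarray, duration_s: float,
                  t_eval: np.ndarray | None = None,
                  rtol: float = 1e-8, atol: float = 1e-10):
        """Integrate the model over one window; returns the solver result."""
        if duration_s < 0:
            raise ValueError("duration must be >= 0")
        if duration_s == 0:
            return None
        sol = solve_ivp(self.rhs, (0.0, duration_s), y0, method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integrator failed: {sol.message}")
        return sol


def circuit_rhs(t: float, y: np.ndarray, model: CircuitModel) -> np.ndarray:
    """Functional entry point to the compiled right-hand side."""
    return model.rhs(t, y)


# -- constitutive closed form ------------------------------------------------


@dataclass(frozen=True)
class ConstitutiveSteadyState:
    m_nm: float
    p_dark_nm: float
    p_nm: float


def steady_state_constitutive(params: KineticParams, g_nm: float,
                              k_dil: float,
                              e_level: float | None = None) -> ConstitutiveSteadyState:
    """Continuous-chemostat fixed point for one unregulated template.

    With the resource clamped at its steady supply level (saturation
    factor ``rho``) and every mobile species diluted at the effective
    continuous rate ``k_dil``:

        M_ss  = k_tx * G * rho / (delta_m + k_dil)
        Pd_ss = k_tl * M_ss * rho / (k_mat + k_dil)
        P_ss  = k_mat * Pd_ss / k_dil

    This is the analytic oracle that the discrete flush/incubate protocol
    must approach as the flush period goes to zero.  It neglects resource
    depletion and translational load (exact in the ``unlimited_resource``
    preset; a good approximation whenever E stays near its supply level
    and W << K_W, i.e. at recommended low template densities).
    """
    if k_dil <= 0:
        raise ValueError("effective dilution rate must be > 0")
    if g_nm < 0:
        raise ValueError("template concentration must be >= 0")
    rho = params.rho(e_level)
    m = params.k_tx * g_nm * rho / (params.delta_m + k_dil)
    pd = params.k_tl * m * rho / (params.k_mat + k_dil)
    p = params.k_mat * pd / k_dil
    return ConstitutiveSteadyState(m_nm=m, p_dark_nm=pd, p_nm=p)


# -- toggle-switch state finding ---------------------------------------------


@dataclass(frozen=True)
class FixedPoint:
    """A long-time endpoint of the circuit dynamics."""

    concentrations: dict[str, float]
    stable: bool
    residual: float

    def __getitem__(self, species: str) -> float:
        return self.concentrations[species]


def find_stable_states(circuit: CircuitSpec,
                       params: KineticParams | None = None,
                       geometry: UnitCellGeometry | None = None,
                       reservoir: Mapping[str, float] | None = None,
                       seed_concentration_nm: float = 2000.0,
                       t_max_h: float = 200.0,
                       rel_cluster_tol: float = 0.05) -> list[FixedPoint]:
    """Locate the distinct long-time states of a (toggle) circuit.

    Integrates the clamped-reservoir (continuous chemostat) model from a
    grid of initial repressor configurations (all corners of
    {0, seed} per produced protein, plus the all-equal midpoint) to
    ``t_max_h``, clusters the endpoints, and classifies each by the sign
    of the leading Jacobian eigenvalue.  Unstable endpoints — e.g. the
    symmetric saddle reached from an exactly symmetric start — are
    returned flagged rather than silently dropped, so callers can filter
    on ``stable``.
    """
    if params is None:
        params = KineticParams()
    if geometry is None:
        geometry = UnitCellGeometry(connecting_length_um=50.0)
    if reservoir is None:
        reservoir = {RESOURCE: params.E_supply}
    model = CircuitModel(circuit, params, [geometry], clamped_reservoir=True)
    model.set_clamped_reservoir(reservoir)

    prot_cols = [int(i) for i in model.i_prot]
    corners = list(itertools.product([0.0, seed_concentration_nm],
                                     repeat=len(prot_cols)))
    mids = [tuple(seed_concentration_nm / 2 for _ in prot_cols)]
    endpoints = []
    for corner in corners + mids:
        y0 = model.initial_state()
        y0 = y0.copy()
        y0[model.index[RESOURCE]] = reservoir.get(RESOURCE, params.E_supply)
        for col, val in zip(prot_cols, corner):
            y0[col] = val
        sol = model.integrate(y0, t_max_h * 3600.0, rtol=1e-8, atol=1e-10)
        endpoints.append(sol.y[:, -1])

    scale = max(1.0, max(np.max(np.abs(e)) for e in endpoints))
    clusters: list[np.ndarray] = []
    for e in endpoints:
        if not any(np.max(np.abs(e - c)) < rel_cluster_tol * scale
                   for c in clusters):
            clusters.append(e)

    states = []
    for y in clusters:
        r = model.rhs(0.0, y)
        residual = float(np.max(np.abs(r)))
        if residual > 1e-6 * scale:
            raise RuntimeError(
                f"endpoint did not converge to a fixed point within "
                f"{t_max_h} h (residual {residual:.3g})")
        lead = _leading_eigenvalue(model, y)
        conc = {s: float(np.clip(y[model.index[s]], 0.0, None))
                for s in model.species}
        states.append(FixedPoint(concentrations=conc,
                                 stable=lead < 0.0, residual=residual))
    return states


def _leading_eigenvalue(model: CircuitModel, y: np.ndarray) -> float:
    n = y.size
    jac = np.zeros((n, n))
    f0 = model.rhs(0.0, y)
    for i in range(n):
        h = 1e-6 * max(abs(y[i]), 1.0)
        yp = y.copy()
        yp[i] += h
        jac[:, i] = (model.rhs(0.0, yp) - f0) / h
    return float(np.max(np.linalg.eigvals(jac).real))
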