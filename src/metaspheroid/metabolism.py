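"""Per-cell gene-metabolism network.

Each cell carries a 53-variable state: a glycolysis + glycogen + TCA +
oxidative-phosphorylation metabolite block, ten enzyme/transporter protein
levels, and ten regulated gene expressions (HIF-1a, AMPK, p53, MYC, PDK and
the genes for GLUT, LDH, PDH, MCT and PFK).  The fast metabolite block is
integrated with an explicit trapezoid (Heun) scheme at the 1.2 s metabolism
step (automatic substep halving
on positivity or finiteness violations); the slow gene/protein block
advances on the 6-min phenotype clock with additive Gaussian noise from a
counter-based per-cell stream.

Key couplings:

* LDH (``r12``) is reversible mass action: positive converts pyruvate to
  lactate, negative regenerates pyruvate from lactate.
* PDH (``r18``) is irreversible and feeds the TCA cycle; oxygen enters only
  through the electron transport reactions, so hypoxia backs the system up
  into fermentation through the NADH redox state.
* MCT (``r21``) co-transports lactate with protons, driven by the
  difference of the intra- and extracellular lactate*proton products;
  positive means export.
* Acidity inhibits glycolysis multiplicatively at PFK via a sigmoid factor
  equal to 1 at physiological pH 7.4.
* HIF-1a degradation requires oxygen and is suppressed by lactate, so
  abundant lactate stimulates glycolytic gene expression even under oxygen.
* ``gamma`` multiplies every gene's production term; it is redrawn at
  division to model gradual epimutational variability.
"""
from __future__ import annotations

import numpy as np

from . import params as P
from . import state as S
from ._kernels import (
    gene_protein_step,
    integrate_metabolism_population,
    metab_rhs,
    ph_factor,
)
from .state import ExchangeRates, FluxRecord, LocalEnvironment, MetabolicState

_PARAMS_CACHE: dict[str, np.ndarray] = {}


class IntegrationError(RuntimeError):
    """Metabolite integration failed below the minimum substep."""


def get_params(path: str | None = None) -> np.ndarray:
    key = path or "__default__"
    if key not in _PARAMS_CACHE:
        _PARAMS_CACHE[key] = P.load_params(path)
    return _PARAMS_CACHE[key]


# Basal (well-fed, normoxic) starting values for the 53 variables, in the
# order of state.VAR_NAMES.  Metabolites in mM; expressions dimensionless.
BASAL_VALUES = np.array([
    1.0,      # glucose_i
    0.20,     # g6p
    0.06,     # f6p
    0.10,     # fbp
    0.15,     # dhap
    0.015,    # gap
    0.01,     # bpg
    0.10,     # pg3
    0.02,     # pg2
    0.03,     # pep
    0.10,     # pyruvate
    0.50,     # lactate_i
    7.943e-5, # proton_i (pH 7.1)
    3.0,      # glycogen
    0.05,     # accoa
    0.30,     # cit
    0.06,     # icit
    0.20,     # akg
    0.05,     # succoa
    0.50,     # suc
    0.10,     # fum
    0.30,     # mal
    0.01,     # oaa
    0.48,     # nad_c
    0.02,     # nadh_c
    0.40,     # nad_m
    0.10,     # nadh_m
    0.08,     # fad
    0.02,     # fadh2
    2.0,      # atp
    0.85,     # adp
    0.15,     # amp
    0.10,     # coa
    1.0,      # glut_p
    1.0,      # hk_p
    1.0,      # pfk_p
    1.0,      # pk_p
    1.0,      # ldh_p
    0.95,     # pdh_p
    0.40,     # pdk_p
    1.0,      # mct_p
    1.0,      # etc_p
    1.0,      # atpase_p
    0.24,     # hif1a
    0.16,     # ampk
    0.26,     # p53
    1.16,     # myc
    0.40,     # pdk
    0.90,     # glut1
    1.10,     # ldh
    0.95,     # pdh
    0.95,     # mct
    0.95,     # pfk
])
assert BASAL_VALUES.shape == (S.N_VARS,)


def init_state(gamma: float, rng_seed: int = 0) -> MetabolicState:
    """Fresh cell state at the tabulated basal values (deterministic)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    del rng_seed  # basal initialization is deterministic
    return MetabolicState(BASAL_VALUES.copy(), gamma=float(gamma))


def reaction_rates(state: MetabolicState, env: LocalEnvironment,
                   params: np.ndarray | None = None) -> FluxRecord:
    """Evaluate all network reaction/transport rates; no state mutation."""
    p = get_params() if params is None else params
    dy = np.zeros(S.N_VARS)
    v = np.zeros(S.N_FLUXES)
    metab_rhs(state.variables, env.as_array(), p, dy, v)
    return FluxRecord(v)


def mct_flux(lactate_i: float, proton_i: float, lactate_e: float,
             proton_e: float, mct_capacity: float,
             params: np.ndarray | None = None) -> float:
    """Reversible lactate-proton symport rate (mM/min; positive = export).

    The driving force is the difference of the lactate*proton products on
    either side of the membrane (protons normalized to the pH-7.4 level);
    the rate saturates in the combined product.
    """
    if min(lactate_i, proton_i, lactate_e, proton_e) < 0 or mct_capacity < 0:
        raise ValueError("concentrations and capacity must be non-negative")
    p = get_params() if params is None else params
    href = p[P.P_PROTON_HREF]
    prod_i = lactate_i * proton_i / href
    prod_e = lactate_e * proton_e / href
    return float(p[P.P_R21_VMAX] * mct_capacity * (prod_i - prod_e)
                 / (p[P.P_R21_KM] + prod_i + prod_e))


def ph_inhibition_factor(ph_i: float, ph_e: float,
                         params: np.ndarray | None = None) -> float:
    p = get_params() if params is None else params
    return float(ph_factor(ph_i, ph_e, p))


def glycolysis_ph_modulation(base_rate: float, ph_i: float, ph_e: float,
                             params: np.ndarray | None = None) -> float:
    """Acid inhibition of glycolysis: multiplicative factor in [0, 1],
    non-decreasing in pH and exactly 1 at physiological pH 7.4."""
    if not (3.0 < ph_i < 9.0 and 3.0 < ph_e < 9.0):
        raise ValueError("pH out of the admissible (3, 9) range")
    return base_rate * ph_inhibition_factor(ph_i, ph_e, params)


def gene_regulation_step(state: MetabolicState, env: LocalEnvironment,
                         gamma: float, dt_s: float, *, seed: int = 0,
                         cell_id: int = 0, tick: int = 0,
                         sigma: float | None = None,
                         params: np.ndarray | None = None) -> MetabolicState:
    """Advance the ten gene expressions and protein levels by ``dt_s``."""
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    p = get_params() if params is None else params
    sig = p[P.P_NOISE_SIGMA] if sigma is None else sigma
    out = state.copy()
    out.gamma = gamma
    states = out.variables[None, :]
    envs = env.as_array()[None, :]
    gene_protein_step(states, envs, np.array([gamma]), np.array([cell_id], dtype=np.int64),
                      dt_s / 60.0, p, sig, seed, tick)
    return out


def step_metabolism(state: MetabolicState, env: LocalEnvironment, dt_s: float = 1.2,
                    *, cell_id: int = 0, params: np.ndarray | None = None,
                    ) -> tuple[MetabolicState, FluxRecord, ExchangeRates]:
    """Integrate the metabolite block over one metabolism step.

    Returns the new state, the interval-averaged flux record, and the net
    cell-volume-referenced exchange rates (mM/min, positive = released into
    the environment).
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    p = get_params() if params is None else params
    out = state.copy()
    states = out.variables[None, :]
    envs = env.as_array()[None, :]
    flux = np.zeros((1, S.N_FLUXES))
    exch = np.zeros((1, 4))
    fail = integrate_metabolism_population(states, envs, dt_s, p, flux, exch)
    if fail >= 0:
        raise IntegrationError(
            f"metabolite integration failed for cell {cell_id}: "
            "step rejected below the minimum substep"
        )
    rec = FluxRecord(flux[0])
    ex = ExchangeRates(oxygen=exch[0, 0], glucose=exch[0, 1],
                       lactate=exch[0, 2], proton=exch[0, 3])
    return out, rec, ex


def relax_cell(state: MetabolicState, env: LocalEnvironment, hours: float,
               *, gamma: float | None = None, sigma: float = 0.0, seed: int = 0,
               cell_id: int = 0, dt_metab_s: float = 1.2, dt_gene_s: float = 360.0,
               params: np.ndarray | None = None) -> tuple[MetabolicState, FluxRecord]:
    """Co-integrate metabolites and gene regulation in a fixed environment.

    Utility for steady-state scans and single-cell protocols; returns the
    final state and the flux record averaged over the last gene interval.
    """
    p = get_params() if params is None else params
    g = state.gamma if gamma is None else gamma
    out = state.copy()
    out.gamma = g
    states = out.variables[None, :]
    envs = env.as_array()[None, :]
    gam = np.array([g])
    cid = np.array([cell_id], dtype=np.int64)
    flux = np.zeros((1, S.N_FLUXES))
    exch = np.zeros((1, 4))
    metab_per_gene = max(1, int(round(dt_gene_s / dt_metab_s)))
    n_gene = max(1, int(round(hours * 3600.0 / dt_gene_s)))
    flux_mean = np.zeros(S.N_FLUXES)
    for tick in range(n_gene):
        flux_mean[:] = 0.0
        for _ in range(metab_per_gene):
            fail = integrate_metabolism_population(states, envs, dt_metab_s, p, flux, exch)
            if fail >= 0:
                raise IntegrationError(f"metabolite integration failed for cell {cell_id}")
            flux_mean += flux[0] / metab_per_gene
        gene_protein_step(states, envs, gam, cid, dt_gene_s / 60.0, p, sigma, seed, tick)
    return out, FluxRecord(flux_mean)
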