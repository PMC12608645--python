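"""Per-cell dynamic state of the gene-metabolism network.

The network tracks 53 variables per cell, split into three blocks:

* 33 metabolites (mM, referenced to cell volume): glycolysis intermediates,
  a glycogen store, TCA-cycle intermediates, redox carriers (cytosolic and
  mitochondrial NAD/NADH, FAD/FADH2), the adenylate pool, free coenzyme A,
  intracellular lactate and free protons.
* 10 enzyme/transporter protein levels (dimensionless expression units),
  one per regulated gene, relaxing toward their gene's expression.
* 10 regulated gene expressions (dimensionless): HIF-1a, AMPK, p53, MYC,
  PDK, and the genes for GLUT, LDH, PDH, MCT and PFK.

LDH and PDH gene expression are the two coordinates of the metabolic
landscape projection.  Oxygen is not a state variable: intracellular oxygen
is assumed to equilibrate with the local extracellular level.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# --- metabolites (0..32) ---
GLC_I = 0      # intracellular glucose
G6P = 1
F6P = 2
FBP = 3
DHAP = 4
GAP = 5
BPG = 6        # 1,3-bisphosphoglycerate
PG3 = 7
PG2 = 8
PEP = 9
PYR = 10
LAC_I = 11     # intracellular lactate
H_I = 12       # intracellular free protons (mM)
GLY = 13       # glycogen store, glucose equivalents
ACCOA = 14
CIT = 15
ICIT = 16
AKG = 17
SUCCOA = 18
SUC = 19
FUM = 20
MAL = 21
OAA = 22
NAD_C = 23
NADH_C = 24
NAD_M = 25
NADH_M = 26
FAD = 27
FADH2 = 28
ATP = 29
ADP = 30
AMP = 31
COA = 32

# --- proteins (33..42) ---
GLUT_P = 33
HK_P = 34
PFK_P = 35
PK_P = 36
LDH_P = 37
PDH_P = 38
PDK_P = 39
MCT_P = 40
ETC_P = 41
ATPASE_P = 42

# --- gene expressions (43..52) ---
HIF1A = 43
AMPK = 44
P53 = 45
MYC = 46
PDK_G = 47
GLUT_G = 48
LDH_G = 49
PDH_G = 50
MCT_G = 51
PFK_G = 52

N_VARS = 53
N_METABOLITES = 33
PROTEIN_SLICE = slice(33, 43)
GENE_SLICE = slice(43, 53)

VAR_NAMES = (
    "glucose_i", "g6p", "f6p", "fbp", "dhap", "gap", "bpg", "pg3", "pg2",
    "pep", "pyruvate", "lactate_i", "proton_i", "glycogen", "accoa", "cit",
    "icit", "akg", "succoa", "suc", "fum", "mal", "oaa", "nad_c", "nadh_c",
    "nad_m", "nadh_m", "fad", "fadh2", "atp", "adp", "amp", "coa",
    "glut_p", "hk_p", "pfk_p", "pk_p", "ldh_p", "pdh_p", "pdk_p", "mct_p",
    "etc_p", "atpase_p",
    "hif1a", "ampk", "p53", "myc", "pdk", "glut1", "ldh", "pdh", "mct", "pfk",
)
assert len(VAR_NAMES) == N_VARS

GENE_NAMES = VAR_NAMES[GENE_SLICE]

# reaction/transport ids in the flux record, in storage order
FLUX_IDS = (
    "r1",   # GLUT facilitated glucose uptake (positive = uptake)
    "r2",   # hexokinase
    "r3",   # phosphoglucose isomerase
    "r4",   # phosphofructokinase (pH-modulated step)
    "r5",   # aldolase
    "r6",   # triose-phosphate isomerase
    "r7",   # GAPDH
    "r8",   # phosphoglycerate kinase
    "r9",   # phosphoglycerate mutase
    "r10",  # enolase
    "r11",  # pyruvate kinase
    "r12",  # lactate dehydrogenase (positive = pyruvate -> lactate)
    "r13",  # glycogen synthesis
    "r14",  # glycogenolysis
    "r15",  # cytosol->mitochondria NADH shuttle
    "r16",  # ATP maintenance demand
    "r17",  # adenylate kinase
    "r18",  # pyruvate dehydrogenase (>= 0)
    "r19",  # citrate synthase
    "r20",  # aconitase
    "r21",  # MCT lactate-proton symport (positive = export)
    "r22",  # isocitrate dehydrogenase
    "r23",  # alpha-KG dehydrogenase
    "r24",  # succinyl-CoA synthetase
    "r25",  # succinate dehydrogenase
    "r26",  # fumarase
    "r27",  # malate dehydrogenase
    "r28",  # electron transport, NADH-fed (ATP-coupled)
    "r29",  # electron transport, FADH2-fed
    "r30",  # proton extrusion (NHE-like pH-i regulation)
)
N_FLUXES = len(FLUX_IDS)
FLUX_INDEX = {name: i for i, name in enumerate(FLUX_IDS)}
R1, R12, R18, R21 = FLUX_INDEX["r1"], FLUX_INDEX["r12"], FLUX_INDEX["r18"], FLUX_INDEX["r21"]

SPECIES_NAMES = ("oxygen", "glucose", "lactate", "proton")


@dataclass
class MetabolicState:
    """View over one cell's 53-variable vector plus its gamma modulation."""

    variables: np.ndarray
    gamma: float = 1.0

    def __post_init__(self) -> None:
        self.variables = np.asarray(self.variables, dtype=np.float64)
        if self.variables.shape != (N_VARS,):
            raise ValueError(f"state vector must have length {N_VARS}")

    def __getitem__(self, name: str) -> float:
        return float(self.variables[VAR_NAMES.index(name)])

    # named accessors required by the network's consumers
    @property
    def glucose_i(self) -> float:
        return float(self.variables[GLC_I])

    @property
    def pyruvate(self) -> float:
        return float(self.variables[PYR])

    @property
    def lactate_i(self) -> float:
        return float(self.variables[LAC_I])

    @property
    def proton_i(self) -> float:
        return float(self.variables[H_I])

    @property
    def atp(self) -> float:
        return float(self.variables[ATP])

    @property
    def ldh(self) -> float:
        return float(self.variables[LDH_G])

    @property
    def pdh(self) -> float:
        return float(self.variables[PDH_G])

    @property
    def hif1a(self) -> float:
        return float(self.variables[HIF1A])

    def genes(self) -> dict[str, float]:
        return dict(zip(GENE_NAMES, self.variables[GENE_SLICE].tolist()))

    def copy(self) -> "MetabolicState":
        return MetabolicState(self.variables.copy(), self.gamma)


@dataclass
class FluxRecord:
    """Instantaneous (or interval-averaged) reaction/transport rates, mM/min."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.rates.shape != (N_FLUXES,):
            raise ValueError(f"flux record must have length {N_FLUXES}")
        if not np.all(np.isfinite(self.rates)):
            bad = [FLUX_IDS[i] for i in np.where(~np.isfinite(self.rates))[0]]
            raise FloatingPointError(f"non-finite reaction rate(s): {bad}")

    def __getitem__(self, rid: str) -> float:
        return float(self.rates[FLUX_INDEX[rid]])

    @property
    def r12(self) -> float:
        return float(self.rates[R12])

    @property
    def r18(self) -> float:
        return float(self.rates[R18])

    @property
    def r21(self) -> float:
        return float(self.rates[R21])

    @property
    def glucose_uptake(self) -> float:
        return float(self.rates[R1])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FLUX_IDS, self.rates.tolist()))


@dataclass
class LocalEnvironment:
    """Extracellular concentrations seen by one cell (all mM)."""

    oxygen: float
    glucose_e: float
    lactate_e: float
    proton_e: float

    def __post_init__(self) -> None:
        for name in ("oxygen", "glucose_e", "lactate_e", "proton_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.oxygen, self.glucose_e, self.lactate_e, self.proton_e],
            dtype=np.float64,
        )


@dataclass
class ExchangeRates:
    """Net cell<->environment rates, mM/min referenced to cell volume.

    Positive = released into the environment (so uptake is negative).
    """

    oxygen: float = 0.0
    glucose: float = 0.0
    lactate: float = 0.0
    proton: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.oxygen, self.glucose, self.lactate, self.proton],
            dtype=np.float64,
        )
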