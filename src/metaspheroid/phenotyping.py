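"""Phenotype classifiers and landscape analysis.

Cells are classified by pyruvate flux partitioning between fermentation
(LDH, r12) and respiration (PDH, r18): fermentative if r12 > r18, with
pronounced fermentation when r12 exceeds 10x r18, and symmetrically for
respiration.  A negative r12 (lactate being converted back to pyruvate)
counts as zero fermentation for labeling; that reverse flux is captured by
the lactate status instead.

Lactate status follows the flux-direction definition of the Warburg effect:
net MCT export = WARBURG, net uptake = REVERSE_WARBURG, and a fermentative
cell whose transport sits inside the neutral band is in the FERMENTATION
state (lactate produced but equilibrated, not excreted).

The metabolic landscape is the 2D histogram of living cells over
(LDH, PDH) gene expression; attractors are its local density maxima above
a prominence threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

from .state import FluxRecord


class PhenotypeLabel(Enum):
    FERM_PP = "fermentation++"
    FERM_P_RESP_M = "fermentation+/respiration-"
    RESP_P_FERM_M = "respiration+/fermentation-"
    RESP_PP = "respiration++"
    DEAD = "dead"


class LactateStatus(Enum):
    WARBURG = "warburg"
    REVERSE_WARBURG = "reverse_warburg"
    FERMENTATION_STATE = "fermentation_state"
    NONE = "none"
    DEAD = "dead"


FERMENTATIVE_LABELS = (PhenotypeLabel.FERM_PP, PhenotypeLabel.FERM_P_RESP_M)
RESPIRATORY_LABELS = (PhenotypeLabel.RESP_PP, PhenotypeLabel.RESP_P_FERM_M)


def classify_phenotype(flux: FluxRecord | None, *, r12: float | None = None,
                       r18: float | None = None) -> PhenotypeLabel:
    """Label a cell from its interval-averaged r12 (LDH) and r18 (PDH).

    The rule is scale-invariant; ties (r12 == r18) fall to the respiratory
    hybrid, a measure-zero event.
    """
    if flux is not None:
        r12, r18 = flux.r12, flux.r18
    if r12 is None or r18 is None or not (np.isfinite(r12) and np.isfinite(r18)):
        raise ValueError("finite r12 and r18 required")
    ferm = max(r12, 0.0)
    if ferm > r18:
        return PhenotypeLabel.FERM_PP if ferm > 10.0 * r18 else PhenotypeLabel.FERM_P_RESP_M
    return PhenotypeLabel.RESP_PP if r18 > 10.0 * ferm else PhenotypeLabel.RESP_P_FERM_M


def classify_lactate_status(net_mct: float, label: PhenotypeLabel,
                            eps: float) -> LactateStatus:
    """Warburg census from the direction of the net MCT flux.

    ``eps`` (mM/min, >= 0) is the neutral band within which transport is
    considered equilibrated.
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    if label == PhenotypeLabel.DEAD:
        return LactateStatus.DEAD
    if net_mct > eps:
        return LactateStatus.WARBURG
    if net_mct < -eps:
        return LactateStatus.REVERSE_WARBURG
    if label in FERMENTATIVE_LABELS:
        return LactateStatus.FERMENTATION_STATE
    return LactateStatus.NONE


def neutral_band(net_mct_living: np.ndarray, *, fraction: float = 0.01,
                 floor: float = 1e-6) -> float:
    """Population-adaptive neutral band: 1% of the median |net MCT| over
    living cells, floored at 1e-6 mM/min."""
    if net_mct_living.size == 0:
        return floor
    return max(fraction * float(np.median(np.abs(net_mct_living))), floor)


def population_fractions(labels, statuses, counts: dict[str, int]) -> dict:
    """Fractions over living cells (each partition sums to 1) plus state
    counts over all agents.  An empty living population is flagged."""
    labels = list(labels)
    statuses = list(statuses)
    n_living = len(labels)
    out = {
        "state_counts": dict(counts),
        "n_living": n_living,
        "empty": n_living == 0,
        "label_fractions": {},
        "status_fractions": {},
    }
    if n_living == 0:
        return out
    for lab in PhenotypeLabel:
        if lab == PhenotypeLabel.DEAD:
            continue
        out["label_fractions"][lab.value] = sum(1 for x in labels if x == lab) / n_living
    for st in LactateStatus:
        if st == LactateStatus.DEAD:
            continue
        out["status_fractions"][st.value] = sum(1 for x in statuses if x == st) / n_living
    return out


@dataclass
class Landscape:
    """2D cell-density histogram over (LDH, PDH) expression."""

    ldh_edges: np.ndarray
    pdh_edges: np.ndarray
    frame: np.ndarray                 # histogram of the latest frame
    integrated: np.ndarray            # sum over accumulated frames
    n_frames: int = 0
    attractors: list[tuple[float, float]] = field(default_factory=list)

    @classmethod
    def empty(cls, ldh_range=(0.0, 8.0), pdh_range=(0.0, 1.5), bins: int = 60) -> "Landscape":
        return cls(
            ldh_edges=np.linspace(*ldh_range, bins + 1),
            pdh_edges=np.linspace(*pdh_range, bins + 1),
            frame=np.zeros((bins, bins)),
            integrated=np.zeros((bins, bins)),
        )

    def accumulate(self, ldh: np.ndarray, pdh: np.ndarray) -> None:
        h, _, _ = np.histogram2d(
            np.clip(ldh, self.ldh_edges[0], self.ldh_edges[-1] - 1e-12),
            np.clip(pdh, self.pdh_edges[0], self.pdh_edges[-1] - 1e-12),
            bins=(self.ldh_edges, self.pdh_edges),
        )
        self.frame = h
        self.integrated += h
        self.n_frames += 1

    def find_attractors(self, *, prominence: float = 0.05,
                        min_separation_bins: int = 3) -> list[tuple[float, float]]:
        """Local maxima of the integrated density above ``prominence`` times
        the global maximum, at least ``min_separation_bins`` apart."""
        h = ndimage.gaussian_filter(self.integrated, sigma=1.0)
        if h.max() <= 0:
            self.attractors = []
            return []
        size = 2 * min_separation_bins + 1
        peaks = (h == ndimage.maximum_filter(h, size=size)) & (h > prominence * h.max())
        li, pi = np.where(peaks)
        lc = 0.5 * (self.ldh_edges[:-1] + self.ldh_edges[1:])
        pc = 0.5 * (self.pdh_edges[:-1] + self.pdh_edges[1:])
        order = np.argsort(-h[li, pi])
        self.attractors = [(float(lc[i]), float(pc[j]))
                           for i, j in zip(li[order], pi[order])]
        return self.attractors


def landscape_density(ldh: np.ndarray, pdh: np.ndarray, *,
                      ldh_range=(0.0, 8.0), pdh_range=(0.0, 1.5),
                      bins: int = 60) -> Landscape:
    """Single-frame landscape for a set of living cells."""
    ls = Landscape.empty(ldh_range, pdh_range, bins)
    ls.accumulate(np.asarray(ldh, dtype=float), np.asarray(pdh, dtype=float))
    return ls
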