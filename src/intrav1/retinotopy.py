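"""Synthetic retinotopic map of V1 and the quadrant sub-network taxonomy.

Each V1 vertex is assigned a visual-field position (DVA, fixation at the
origin, x positive to the right, y positive upward) within the central 4 DVA
of eccentricity.  The cortical mapping is contralateral: vertices of the
left hemisphere represent the right visual hemifield (vf_x > 0) and vice
versa.  Edges between vertices are classified into ten sub-networks by the
unordered pair of visual-field quadrants their endpoints map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

QUADRANTS = ("UL", "UR", "LL", "LR")

#: sub-network label for every unordered quadrant pair (10 classes:
#: 4 within-quadrant + 6 between-quadrant)
SUBNETWORK_OF_PAIR = {
    frozenset(["UL"]): "ULq",
    frozenset(["UR"]): "URq",
    frozenset(["LL"]): "LoLeq",
    frozenset(["LR"]): "LoRq",
    frozenset(["UL", "UR"]): "LRup",
    frozenset(["LL", "LR"]): "LRlo",
    frozenset(["UL", "LL"]): "UDle",
    frozenset(["UR", "LR"]): "UDr",
    frozenset(["UL", "LR"]): "DiagP",
    frozenset(["UR", "LL"]): "DiagS",
}
SUBNETWORK_LABELS = (
    "ULq", "URq", "LoLeq", "LoRq",
    "LRup", "LRlo", "UDle", "UDr", "DiagP", "DiagS",
)
#: sub-networks whose endpoints lie in different visual hemifields, hence in
#: different cortical hemispheres under the contralateral mapping
INTERHEMISPHERIC = frozenset({"LRup", "LRlo", "DiagP", "DiagS"})
INTRAHEMISPHERIC = frozenset(set(SUBNETWORK_LABELS) - INTERHEMISPHERIC)


def quadrant_of(vf_x: np.ndarray, vf_y: np.ndarray) -> np.ndarray:
    """Quadrant labels from signed visual-field coordinates."""
    vf_x = np.asarray(vf_x)
    vf_y = np.asarray(vf_y)
    vertical = np.where(vf_y > 0, "U", "L")
    horizontal = np.where(vf_x > 0, "R", "L")
    return np.char.add(vertical, horizontal)


def subnetwork_label(quadrant_a: str, quadrant_b: str) -> str:
    """Sub-network class of an edge from its endpoint quadrants."""
    return SUBNETWORK_OF_PAIR[frozenset((quadrant_a, quadrant_b))]


@dataclass(frozen=True)
class RetinotopicMap:
    """Vertex -> visual-field lookup for one synthetic V1 ROI."""

    vertex_id: np.ndarray
    hemisphere: np.ndarray  # 'L' or 'R' (cortical)
    vf_x: np.ndarray
    vf_y: np.ndarray
    max_ecc: float

    def __post_init__(self) -> None:
        ecc = self.eccentricity
        if np.any(ecc > self.max_ecc + 1e-9):
            raise ValueError("vertex eccentricity exceeds the ROI limit")
        contralateral = np.where(self.vf_x > 0, "L", "R")
        if not np.array_equal(contralateral, self.hemisphere):
            raise ValueError("hemisphere labels violate the contralateral mapping")

    @property
    def n_vertices(self) -> int:
        return self.vertex_id.size

    @property
    def eccentricity(self) -> np.ndarray:
        return np.hypot(self.vf_x, self.vf_y)

    @property
    def quadrant(self) -> np.ndarray:
        return quadrant_of(self.vf_x, self.vf_y)


def build_retinotopic_map(
    n_vertices: int, max_ecc: float = 4.0, seed: int = 0
) -> RetinotopicMap:
    """Quasi-uniform jittered tiling of the central visual-field disc.

    Half the vertices land in each hemifield (one cortical hemisphere each).
    A sunflower (golden-angle) spiral per hemifield gives near-uniform
    density in area; seed-controlled jitter breaks the lattice.  Density is
    uniform in visual-field area, not cortical-magnification weighted.
    """
    if n_vertices < 8:
        raise ValueError("need at least 8 vertices")
    if n_vertices % 2:
        raise ValueError("n_vertices must be even (split across hemispheres)")
    rng = np.random.default_rng(seed)
    m = n_vertices // 2
    golden = (np.sqrt(5.0) - 1.0) / 2.0
    k = np.arange(m)
    r = max_ecc * np.sqrt((k + 0.5) / m)
    theta = -np.pi / 2 + np.pi * ((k * golden) % 1.0)  # right hemifield fan
    jitter_sd = 0.2 * max_ecc / np.sqrt(m)

    halves = []
    for sign in (+1.0, -1.0):
        x = r * np.cos(theta) * sign
        y = r * np.sin(theta)
        x = x + rng.normal(0.0, jitter_sd, m)
        y = y + rng.normal(0.0, jitter_sd, m)
        x = sign * np.maximum(np.abs(x), 1e-3)  # stay inside the hemifield
        y = np.where(np.abs(y) < 1e-3, np.sign(y + 1e-12) * 1e-3, y)
        ecc = np.hypot(x, y)
        over = ecc > max_ecc
        shrink = np.where(over, (max_ecc - 1e-6) / ecc, 1.0)
        halves.append((x * shrink, y * shrink))

    vf_x = np.concatenate([halves[0][0], halves[1][0]])
    vf_y = np.concatenate([halves[0][1], halves[1][1]])
    hemisphere = np.where(vf_x > 0, "L", "R")
    return RetinotopicMap(
        vertex_id=np.arange(n_vertices),
        hemisphere=hemisphere,
        vf_x=vf_x,
        vf_y=vf_y,
        max_ecc=max_ecc,
    )
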