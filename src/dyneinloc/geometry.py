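"""9+2 cross-section geometry: arm vectors, dynein moments, doublet numbering.

The axoneme's nine doublet microtubules sit on a ring with approximate C9
symmetry (40° per step).  Dynein arms extend from the A-tubule of doublet n
with arm vector

    aₙ = (0, −a sin θₙ, a cos θₙ),   θₙ = (40n − 20)°,

in the right-handed frame whose x-axis runs base→tip along the axoneme and
whose y-axis points into the reverse bend.  Dynein forces are minus-end
directed, −F x̂, so each active dynein contributes a moment aₙ × (−F x̂).

Because the outer arms are missing between the bridge doublets (sperm DM5–DM6),
the arm vectors of the remaining eight doublets sum to a ẑ: a fully active
ring produces the moment a ẑ × (−F x̂) = −a F ŷ, which has no ẑ component and
hence bends nothing in the beat (x–y) plane.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CONVENTIONS",
    "BRIDGE_PAIRS",
    "arm_vector",
    "dynein_moment",
    "map_numbering",
    "active_ring_indices",
]

CONVENTIONS = ("sperm", "chlamydomonas")

#: Doublet pairs joined by the permanent bridge (no outer arms in between).
BRIDGE_PAIRS = {"sperm": (5, 6), "chlamydomonas": (1, 2)}

# Sperm→Chlamydomonas doublet correspondence.  Only two anchors are fixed by
# the ultrastructure: DM1 ↔ cDM5 and the bridge pair {DM5, DM6} ↔ {cDM1, cDM2}.
# No rotation or reflection of the 9-ring satisfies both (the two numbering
# origins are offset by half a doublet), so the table below is one consistent
# completion: the ring reversal n ↦ 6−n (mod 9) that fixes DM1→cDM5 and
# DM5→cDM1, with the images of DM4 and DM6 swapped to bring DM6 onto cDM2.
_SPERM_TO_CHLAMY = {1: 5, 2: 4, 3: 3, 4: 9, 5: 1, 6: 2, 7: 8, 8: 7, 9: 6}
_CHLAMY_TO_SPERM = {c: s for s, c in _SPERM_TO_CHLAMY.items()}


def _check_index(n: int) -> int:
    n = int(n)
    if not 1 <= n <= 9:
        raise IndexError(f"doublet index must be in 1..9, got {n}")
    return n


def arm_vector(n: int, a: float = 1.0) -> np.ndarray:
    """Arm vector of the dynein anchored on doublet ``n`` (sperm numbering).

    Returns the 3-vector (0, −a sin(40n−20)°, a cos(40n−20)°), μm.  Its
    magnitude is ``a`` for every doublet.
    """
    n = _check_index(n)
    theta = np.deg2rad(40.0 * n - 20.0)
    return np.array([0.0, -a * np.sin(theta), a * np.cos(theta)])


def active_ring_indices() -> tuple[int, ...]:
    """Doublets carrying outer arms: all except the bridge gap (sperm 5–6)."""
    return (1, 2, 3, 4, 6, 7, 8, 9)


def dynein_moment(arm: np.ndarray, F: float) -> np.ndarray:
    """Moment generated by one dynein: arm × (−F x̂), pN·μm.

    The dynein force is minus-end directed (−F along the axonemal axis), so
    the moment lies in the y–z plane; its ẑ component is what bends the
    axoneme in the beat (x–y) plane.
    """
    arm = np.asarray(arm, dtype=float)
    if arm.shape != (3,):
        raise ValueError(f"arm must be a 3-vector, got shape {arm.shape}")
    if F < 0:
        raise ValueError(f"force magnitude F must be >= 0, got {F}")
    force = np.array([-F, 0.0, 0.0])
    return np.cross(arm, force)


def map_numbering(n: int, from_convention: str, to_convention: str) -> int:
    """Map a doublet index between the sperm and Chlamydomonas conventions.

    The mapping is a bijection on 1..9 satisfying the two structural anchors
    (sperm DM1 ↔ cDM5; the bridge pairs map onto each other as sets) and is
    its own consistent completion elsewhere — see module notes.
    """
    n = _check_index(n)
    for conv in (from_convention, to_convention):
        if conv not in CONVENTIONS:
            raise ValueError(f"unknown convention {conv!r}; expected one of {CONVENTIONS}")
    if from_convention == to_convention:
        return n
    if from_convention == "sperm":
        return _SPERM_TO_CHLAMY[n]
    return _CHLAMY_TO_SPERM[n]
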