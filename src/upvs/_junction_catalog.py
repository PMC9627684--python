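"""Catalogue of junction direction triples that thin to a single 3-neighbour voxel.

Each entry is (parent, child_a, child_b): integer lattice step directions
(axis or face-diagonal) for one bifurcation of a capsule-rasterized vessel
tree.  A junction built from one of these triples, with integer node
coordinates, tube radius 3 voxels and arm length >= 10 steps, reduces under
3D medial-axis thinning to exactly one voxel with three skeleton neighbours.
The catalogue was derived by exhaustive enumeration of all 216 candidate
triples with branching angle in (28, 80) degrees and sibling separation
>= 44 degrees, checked at arm lengths 10, 13 and 16 steps
(scripts/derive_clean_junctions.py); 96 of 216 qualify.
"""

CLEAN_JUNCTION_TRIPLES: tuple[tuple[tuple[int, int, int], ...], ...] = (
    ((-1, -1, 0), (-1, 0, -1), (-1, 0, 0)),
    ((-1, -1, 0), (-1, 0, -1), (-1, 0, 1)),
    ((-1, -1, 0), (-1, 0, -1), (0, -1, 1)),
    ((-1, -1, 0), (-1, 0, 0), (-1, 0, 1)),
    ((-1, -1, 0), (-1, 0, 1), (0, -1, -1)),
    ((-1, -1, 0), (0, -1, -1), (0, -1, 0)),
    ((-1, -1, 0), (0, -1, -1), (0, -1, 1)),
    ((-1, -1, 0), (0, -1, 0), (0, -1, 1)),
    ((-1, 0, -1), (-1, -1, 0), (-1, 1, 0)),
    ((-1, 0, -1), (-1, -1, 0), (0, 1, -1)),
    ((-1, 0, -1), (-1, 1, 0), (0, -1, -1)),
    ((-1, 0, -1), (0, -1, -1), (0, 1, -1)),
    ((-1, 0, 0), (-1, -1, 0), (-1, 1, 0)),
    ((-1, 0, 0), (-1, 0, -1), (-1, 0, 1)),
    ((-1, 0, 1), (-1, -1, 0), (-1, 1, 0)),
    ((-1, 0, 1), (-1, -1, 0), (0, 1, 1)),
    ((-1, 0, 1), (-1, 1, 0), (0, -1, 1)),
    ((-1, 0, 1), (0, -1, 1), (0, 1, 1)),
    ((-1, 1, 0), (-1, 0, -1), (-1, 0, 0)),
    ((-1, 1, 0), (-1, 0, -1), (-1, 0, 1)),
    ((-1, 1, 0), (-1, 0, -1), (0, 1, 1)),
    ((-1, 1, 0), (-1, 0, 0), (-1, 0, 1)),
    ((-1, 1, 0), (-1, 0, 1), (0, 1, -1)),
    ((-1, 1, 0), (0, 1, -1), (0, 1, 0)),
    ((-1, 1, 0), (0, 1, -1), (0, 1, 1)),
    ((-1, 1, 0), (0, 1, 0), (0, 1, 1)),
    ((0, -1, -1), (-1, -1, 0), (0, -1, 0)),
    ((0, -1, -1), (-1, -1, 0), (1, -1, 0)),
    ((0, -1, -1), (-1, -1, 0), (1, 0, -1)),
    ((0, -1, -1), (-1, 0, -1), (0, 0, -1)),
    ((0, -1, -1), (-1, 0, -1), (1, -1, 0)),
    ((0, -1, -1), (-1, 0, -1), (1, 0, -1)),
    ((0, -1, -1), (0, -1, 0), (1, -1, 0)),
    ((0, -1, -1), (0, 0, -1), (1, 0, -1)),
    ((0, -1, 0), (-1, -1, 0), (1, -1, 0)),
    ((0, -1, 0), (0, -1, -1), (0, -1, 1)),
    ((0, -1, 1), (-1, -1, 0), (0, -1, 0)),
    ((0, -1, 1), (-1, -1, 0), (1, -1, 0)),
    ((0, -1, 1), (-1, -1, 0), (1, 0, 1)),
    ((0, -1, 1), (-1, 0, 1), (0, 0, 1)),
    ((0, -1, 1), (-1, 0, 1), (1, -1, 0)),
    ((0, -1, 1), (-1, 0, 1), (1, 0, 1)),
    ((0, -1, 1), (0, -1, 0), (1, -1, 0)),
    ((0, 0, -1), (-1, 0, -1), (1, 0, -1)),
    ((0, 0, -1), (0, -1, -1), (0, 1, -1)),
    ((0, 0, 1), (-1, 0, 1), (1, 0, 1)),
    ((0, 0, 1), (0, -1, 1), (0, 1, 1)),
    ((0, 1, -1), (-1, 0, -1), (0, 0, -1)),
    ((0, 1, -1), (-1, 0, -1), (1, 0, -1)),
    ((0, 1, -1), (-1, 0, -1), (1, 1, 0)),
    ((0, 1, -1), (-1, 1, 0), (0, 1, 0)),
    ((0, 1, -1), (-1, 1, 0), (1, 0, -1)),
    ((0, 1, -1), (-1, 1, 0), (1, 1, 0)),
    ((0, 1, -1), (0, 0, -1), (1, 0, -1)),
    ((0, 1, -1), (0, 1, 0), (1, 1, 0)),
    ((0, 1, 0), (-1, 1, 0), (1, 1, 0)),
    ((0, 1, 0), (0, 1, -1), (0, 1, 1)),
    ((0, 1, 1), (-1, 0, 1), (0, 0, 1)),
    ((0, 1, 1), (-1, 0, 1), (1, 0, 1)),
    ((0, 1, 1), (-1, 0, 1), (1, 1, 0)),
    ((0, 1, 1), (-1, 1, 0), (0, 1, 0)),
    ((0, 1, 1), (-1, 1, 0), (1, 0, 1)),
    ((0, 1, 1), (-1, 1, 0), (1, 1, 0)),
    ((0, 1, 1), (0, 1, 0), (1, 1, 0)),
    ((1, -1, 0), (0, -1, -1), (0, -1, 0)),
    ((1, -1, 0), (0, -1, -1), (0, -1, 1)),
    ((1, -1, 0), (0, -1, -1), (1, 0, 1)),
    ((1, -1, 0), (0, -1, 0), (0, -1, 1)),
    ((1, -1, 0), (0, -1, 0), (1, 0, -1)),
    ((1, -1, 0), (0, -1, 0), (1, 0, 1)),
    ((1, -1, 0), (0, -1, 1), (1, 0, -1)),
    ((1, -1, 0), (1, 0, -1), (1, 0, 0)),
    ((1, -1, 0), (1, 0, -1), (1, 0, 1)),
    ((1, 0, -1), (0, -1, -1), (0, 1, -1)),
    ((1, 0, -1), (0, -1, -1), (1, 1, 0)),
    ((1, 0, -1), (0, 0, -1), (1, -1, 0)),
    ((1, 0, -1), (0, 0, -1), (1, 1, 0)),
    ((1, 0, -1), (0, 1, -1), (1, -1, 0)),
    ((1, 0, -1), (1, -1, 0), (1, 1, 0)),
    ((1, 0, 0), (1, -1, 0), (1, 1, 0)),
    ((1, 0, 0), (1, 0, -1), (1, 0, 1)),
    ((1, 0, 1), (0, -1, 1), (0, 1, 1)),
    ((1, 0, 1), (0, -1, 1), (1, 1, 0)),
    ((1, 0, 1), (0, 0, 1), (1, -1, 0)),
    ((1, 0, 1), (0, 0, 1), (1, 1, 0)),
    ((1, 0, 1), (0, 1, 1), (1, -1, 0)),
    ((1, 0, 1), (1, -1, 0), (1, 1, 0)),
    ((1, 1, 0), (0, 1, -1), (0, 1, 0)),
    ((1, 1, 0), (0, 1, -1), (0, 1, 1)),
    ((1, 1, 0), (0, 1, -1), (1, 0, 1)),
    ((1, 1, 0), (0, 1, 0), (0, 1, 1)),
    ((1, 1, 0), (0, 1, 0), (1, 0, -1)),
    ((1, 1, 0), (0, 1, 0), (1, 0, 1)),
    ((1, 1, 0), (0, 1, 1), (1, 0, -1)),
    ((1, 1, 0), (1, 0, -1), (1, 0, 0)),
    ((1, 1, 0), (1, 0, -1), (1, 0, 1)),
)
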