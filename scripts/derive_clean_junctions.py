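#!/usr/bin/env python
"""Regenerate the clean-junction catalogue in ``upvs/_junction_catalog.py``.

Enumerates all candidate bifurcation direction triples (incoming lattice
direction plus two child lattice directions drawn from the 18 axis and
face-diagonal unit steps, branching angle between 28 and 80 degrees,
sibling separation at least 44 degrees) and keeps those whose capsule
rasterization (radius 3, integer nodes) thins to exactly one voxel with
three skeleton neighbours at arm lengths 10, 13 and 16 steps.
"""

import collections
import itertools

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

KERNEL = np.ones((3, 3, 3))
KERNEL[1, 1, 1] = 0

DIRECTIONS = [np.array(v) for v in itertools.product((-1, 0, 1), repeat=3)
              if 1 <= sum(abs(c) for c in v) <= 2]


def unit(v):
    return v / np.linalg.norm(v)


def capsule(shape, p0, p1, r):
    zz, yy, xx = np.indices(shape, dtype=float)
    p = np.stack([zz, yy, xx], -1)
    a, b = np.asarray(p0, float), np.asarray(p1, float)
    ab = b - a
    t = np.clip(((p - a) @ ab) / (float(ab @ ab) or 1.0), 0, 1)
    return np.linalg.norm(p - (a + t[..., None] * ab), axis=-1) <= r


def is_clean(dp, c1, c2, steps, r=3):
    shape = (2 * steps + 14,) * 3
    center = np.asarray(shape) // 2
    vol = (capsule(shape, center - dp * steps, center, r)
           | capsule(shape, center, center + c1 * steps, r)
           | capsule(shape, center, center + c2 * steps, r))
    sk = skeletonize(vol)
    nbr = ndimage.convolve(sk.astype(int), KERNEL, mode="constant")
    cnt = collections.Counter(nbr[sk].tolist())
    return (cnt.get(1, 0) == 3 and cnt.get(3, 0) == 1
            and cnt.get(4, 0) == 0 and max(cnt) <= 3)


def main():
    catalog = []
    for dp in DIRECTIONS:
        udp = unit(dp)
        cands = [c for c in DIRECTIONS if 0.17 <= unit(c) @ udp <= 0.88]
        for c1, c2 in itertools.combinations(cands, 2):
            if unit(c1) @ unit(c2) > 0.72:
                continue
            if all(is_clean(dp, c1, c2, s) for s in (10, 13, 16)):
                catalog.append((tuple(dp), tuple(c1), tuple(c2)))
    print(f"# {len(catalog)} clean triples")
    for dp, c1, c2 in catalog:
        print(f"    ({dp}, {c1}, {c2}),")


if __name__ == "__main__":
    main()
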