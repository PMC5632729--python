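"""IR/SSC junction architecture: ndh inventory, plastome typology (A/B/C),
the 5'-ycf1-to-J_SA distance, and the IR-shift vs retained-ndh-length
origin-constrained regression.

Typology: type A has all 11 ndh genes intact; type B has none of them (all
absent); type C retains a partial complement (intact subset and/or
pseudogene remnants). The alternate reading "B = zero intact genes,
remnants notwithstanding" is selectable via ``rule="zero_intact"``.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
from scipy import stats

from .model import (
    AnnotatedPlastome,
    JunctionProfile,
    NDH_GENES,
    OriginFit,
    RegionPartition,
)


def profile_junctions(p: AnnotatedPlastome,
                      part: RegionPartition) -> JunctionProfile:
    """Junction coordinates, ndh inventory and the signed 5'-ycf1-to-J_SA
    distance (positive when J_SA lies downstream of ycf1's 5' end, i.e.
    inside the gene body) of one canonical plastome."""
    if part is None:
        raise ValueError("profile_junctions requires a region partition")
    ycf1 = None
    for f in p.features:
        if f.name == "ycf1" and (ycf1 is None or (ycf1.pseudogene and not f.pseudogene)):
            ycf1 = f
    ycf1_to_jsa = None
    if ycf1 is not None:
        fp = ycf1.five_prime()
        j = part.j_sa
        ycf1_to_jsa = (j - fp) if ycf1.strand == "+" else (fp - j + 1)
    else:
        warnings.warn(f"{p.identifier}: no ycf1 annotated; distance flagged")

    status: dict[str, str] = {}
    retained = 0
    for name in NDH_GENES:
        copies = [f for f in p.features if f.name == name]
        if not copies:
            status[name] = "absent"
            continue
        intact = [f for f in copies if not f.pseudogene]
        status[name] = "intact" if intact else "pseudogene"
        retained += (intact[0] if intact else copies[0]).total_length
    return JunctionProfile(
        plastome_id=p.identifier,
        j_sa=part.j_sa,
        j_sb=part.j_sb,
        ycf1_to_jsa=ycf1_to_jsa,
        ndh_status=status,
        retained_ndh_length=retained,
    )


def classify_type(prof: JunctionProfile, rule: str = "absent") -> str:
    """Assign the plastome type label A, B or C from the ndh inventory."""
    values = list(prof.ndh_status.values())
    if len(values) != len(NDH_GENES):
        raise ValueError("incomplete ndh inventory")
    n_intact = sum(v == "intact" for v in values)
    if n_intact == len(NDH_GENES):
        label = "A"
    elif rule == "absent":
        label = "B" if all(v == "absent" for v in values) else "C"
    elif rule == "zero_intact":
        label = "B" if n_intact == 0 else "C"
    else:
        raise ValueError(f"unknown typology rule {rule!r}")
    prof.type_label = label
    return label


def ir_shift(prof: JunctionProfile, reference_ycf1_to_jsa: int) -> int:
    """IR expansion/contraction relative to a type-A reference distance."""
    if prof.ycf1_to_jsa is None:
        raise ValueError(f"{prof.plastome_id}: ycf1 distance unavailable")
    return prof.ycf1_to_jsa - reference_ycf1_to_jsa


def fit_origin_regression(points: list[tuple[float, float]],
                          n_permutations: int = 999,
                          seed: int = 0) -> OriginFit:
    """Least squares for y = b*x through the origin.

    R^2 is computed against the origin-constrained fit (uncentered total sum
    of squares). The p-value is a seeded permutation test on R^2 (y values
    shuffled against x).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.all(x == 0):
        raise ValueError("slope undefined: all x are zero")

    def fit(yv: np.ndarray) -> tuple[float, float]:
        b = float(np.dot(x, yv) / np.dot(x, x))
        ss_tot = float(np.dot(yv, yv))
        if ss_tot == 0:
            return b, 1.0
        resid = yv - b * x
        return b, 1.0 - float(np.dot(resid, resid)) / ss_tot

    slope, r2 = fit(y)
    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            _, r2p = fit(rng.permutation(y))
            if r2p >= r2:
                exceed += 1
        p_value = (1 + exceed) / (n_permutations + 1)
    return OriginFit(slope=slope, r_squared=r2, n=len(points), p_value=p_value)


def compare_ir_lengths(groups: dict[str, list[float]]) -> dict[str, dict]:
    """Two-sided Mann-Whitney tests between every pair of type-labelled
    groups of junction-distance values."""
    out: dict[str, dict] = {}
    for a, b in combinations(sorted(groups), 2):
        va, vb = groups[a], groups[b]
        if len(va) < 2 or len(vb) < 2:
            warnings.warn(f"group pair {a}/{b} skipped: fewer than 2 values")
            continue
        u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        out[f"{a}_vs_{b}"] = {"u": float(u), "p": float(p),
                              "n": (len(va), len(vb))}
    return out
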