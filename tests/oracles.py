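"""Independent brute-force and alternative-algorithm oracles.

Everything here is deliberately naive (triple loops, explicit algebra)
and shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def brute_min_distance(coords, idx_a, idx_b):
    return min(dist(coords[i], coords[j]) for i in idx_a for j in idx_b)


def brute_contact_count(coords, elements, idx_a, idx_b, cutoff):
    n = 0
    for i in idx_a:
        if elements[i] == "H":
            continue
        for j in idx_b:
            if elements[j] == "H" or i == j:
                continue
            if dist(coords[i], coords[j]) <= cutoff:
                n += 1
    return n


def _angle(apex, a, b):
    v1 = np.asarray(a) - np.asarray(apex)
    v2 = np.asarray(b) - np.asarray(apex)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def brute_hbond_pairs(coords, elements, donor_idx, acceptor_idx,
                      da_cut=3.0, angle_cut=120.0, h_bond_cut=1.2):
    """Set of (donor, acceptor) pairs satisfying the hydrogen-bond criteria.

    Donors: N/O with >= 1 hydrogen within ``h_bond_cut`` in this frame;
    acceptors: N/O/F.  Distance strictly <, angle strictly >.
    """
    hydrogens = [i for i, e in enumerate(elements) if e == "H"]
    pairs = set()
    for d in donor_idx:
        if elements[d] not in ("N", "O"):
            continue
        bonded_h = [h for h in hydrogens if dist(coords[d], coords[h]) <= h_bond_cut]
        for a in acceptor_idx:
            if elements[a] not in ("N", "O", "F") or a == d:
                continue
            if not dist(coords[d], coords[a]) < da_cut:
                continue
            for h in bonded_h:
                if h == a:
                    continue
                if _angle(coords[h], coords[d], coords[a]) > angle_cut:
                    pairs.add((d, a))
                    break
    return pairs


def brute_xbond_pairs(coords, elements, halogen_idx, acceptor_idx,
                      dist_cut=3.5, angle_cut=140.0, cx_cut=2.0):
    """Set of (halogen, acceptor) pairs satisfying the σ-hole criteria."""
    carbons = [i for i, e in enumerate(elements) if e == "C"]
    pairs = set()
    for x in halogen_idx:
        if elements[x] not in ("F", "Cl", "Br", "I"):
            continue
        if not carbons:
            continue
        c = min(carbons, key=lambda j: dist(coords[x], coords[j]))
        if dist(coords[x], coords[c]) > cx_cut:
            continue
        for a in acceptor_idx:
            if elements[a] not in ("N", "O", "F") or a in (x, c):
                continue
            if dist(coords[x], coords[a]) > dist_cut:
                continue
            if _angle(coords[x], coords[c], coords[a]) >= angle_cut:
                pairs.add((x, a))
    return pairs


def brute_bridging_waters(coords, res_ids, probe_idx, lig_idx, pro_idx, cut=3.5):
    ids = set()
    for o in probe_idx:
        near_lig = any(dist(coords[o], coords[i]) <= cut for i in lig_idx)
        near_pro = any(dist(coords[o], coords[i]) <= cut for i in pro_idx)
        if near_lig and near_pro:
            ids.add(int(res_ids[o]))
    return ids


def quaternion_superpose_rmsd(mobile, reference):
    """Optimal superposition RMSD via Horn's quaternion method.

    An algorithmically independent check on SVD-based least-squares
    fitting: builds the 4x4 key matrix from the correlation of centred
    coordinates and takes its largest eigenvalue.
    """
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    n = len(p)
    e0 = (p ** 2).sum() + (q ** 2).sum()
    msd = max(0.0, (e0 - 2.0 * lam) / n)
    return math.sqrt(msd)


def random_molecular_frame(rng, n_atoms=40, box=8.0):
    """Random coordinates + elements with enough N/O/F/H for all detectors.

    Always contains at least two hydrogens: a hydrogen-free topology puts
    the hydrogen-bond detector into its documented distance-only mode,
    which is tested separately against different expectations.
    """
    elements = list(rng.choice(
        ["C", "N", "O", "F", "H"], size=n_atoms, p=[0.3, 0.2, 0.2, 0.1, 0.2]
    ))
    if elements.count("H") < 2:
        elements[-1] = "H"
        elements[-2] = "H"
    coords = rng.uniform(0.0, box, size=(n_atoms, 3))
    return coords, elements
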