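"""Independent brute-force reference for the full train-then-score pipeline.

Everything here is written longhand in plain Python (double loops over
residues, edge-scan binning, direct transcription of the energy formula) and
deliberately shares no geometry, binning or statistics code with the package
under test.  It is the oracle the package's pipeline must match to 1e-9 on
small inputs; it only consumes the residue data objects (types, seq ids,
atom positions).
"""

import math

AA20 = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"]

TWO_PI = 2.0 * math.pi


def bf_center(res):
    xs = ys = zs = 0.0
    n = 0
    for a in res.atoms:
        x, y, z = (float(v) for v in a.position)
        xs += x; ys += y; zs += z
        n += 1
    return (xs / n, ys / n, zs / n)


def _sub(a, b):
    return (a[0] - b[0], a[1] - b[1], a[2] - b[2])


def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _cross(a, b):
    return (a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0])


def _norm(a):
    return math.sqrt(_dot(a, a))


def _unit(a):
    n = _norm(a)
    return (a[0] / n, a[1] / n, a[2] / n)


def bf_frame(res):
    """(origin, ex, ey, ez) or None if N/CA missing or degenerate."""
    n_pos = ca_pos = None
    for a in res.atoms:
        if a.name == "N":
            n_pos = tuple(float(v) for v in a.position)
        elif a.name == "CA":
            ca_pos = tuple(float(v) for v in a.position)
    if n_pos is None or ca_pos is None:
        return None
    o = bf_center(res)
    xv = _sub(n_pos, o)
    if _norm(xv) < 1e-6:
        return None
    ex = _unit(xv)
    v = _sub(ca_pos, o)
    proj = _dot(v, ex)
    yv = (v[0] - proj * ex[0], v[1] - proj * ex[1], v[2] - proj * ex[2])
    if _norm(yv) < 1e-6:
        return None
    ey = _unit(yv)
    ez = _cross(ex, ey)
    return (o, ex, ey, ez)


def bf_spherical(frame, point):
    o, ex, ey, ez = frame
    d = _sub(tuple(float(v) for v in point), o)
    lx, ly, lz = _dot(d, ex), _dot(d, ey), _dot(d, ez)
    r = math.sqrt(lx * lx + ly * ly + lz * lz)
    if r == 0.0:
        return (0.0, 0.0, 0.0)
    theta = math.acos(max(-1.0, min(1.0, lz / r)))
    if lx == 0.0 and ly == 0.0:
        phi = 0.0
    else:
        phi = math.atan2(ly, lx) % TWO_PI
    return (r, theta, phi)


def bf_bin(theta, phi, n_theta, n_phi):
    """Edge-scan binning: walk the bin edges until the angle fits."""
    dt = math.pi / n_theta
    dp = TWO_PI / n_phi
    t_bin = n_theta - 1
    for t in range(n_theta):
        if t * dt <= theta < (t + 1) * dt:
            t_bin = t
            break
    p_bin = n_phi - 1
    for p in range(n_phi):
        if p * dp <= phi < (p + 1) * dp:
            p_bin = p
            break
    return t_bin, p_bin


def bf_cutoff(mode, r_fixed, radii, ti, tj):
    if mode == "fixed":
        return r_fixed
    return radii[ti] + radii[tj]


def bf_contacts(chain, mode="fixed", r_fixed=6.0, radii=None, include_adjacent=True):
    """All ordered contacts by an O(n^2) double loop; recomputes everything."""
    res = list(chain.residues)
    out = []
    for m in range(len(res)):
        fr = bf_frame(res[m])
        if fr is None:
            continue
        cm = bf_center(res[m])
        for n in range(len(res)):
            if n == m:
                continue
            if not include_adjacent and abs(m - n) == 1:
                continue
            cn = bf_center(res[n])
            d = _norm(_sub(cm, cn))
            if d <= bf_cutoff(mode, r_fixed, radii, res[m].res_type, res[n].res_type):
                sph = bf_spherical(fr, cn)
                out.append((res[m].res_type, res[n].res_type,
                            res[m].seq_id, res[n].seq_id, sph))
    return out


def bf_solid_angle(t_bin, n_theta, n_phi):
    dt = math.pi / n_theta
    return (math.cos(t_bin * dt) - math.cos((t_bin + 1) * dt)) / 2.0 / n_phi


def bf_train(chains, n_theta=20, n_phi=20, mode="fixed", r_fixed=6.0, radii=None,
             alpha=None, missing_pair_energy=0.0, include_adjacent=True):
    """Counts -> probabilities -> energies, direct formula transcription."""
    B = n_theta * n_phi
    if alpha is None:
        alpha = 1.0 / B
    n_i = {t: 0 for t in AA20}
    n_ij = {}
    h = {}
    n_res_total = 0
    n_contacts = 0
    for chain in chains:
        for r in chain.residues:
            n_i[r.res_type] += 1
            n_res_total += 1
        for (ti, tj, _si, _sj, sph) in bf_contacts(chain, mode, r_fixed, radii, include_adjacent):
            tb, pb = bf_bin(sph[1], sph[2], n_theta, n_phi)
            n_ij[(ti, tj)] = n_ij.get((ti, tj), 0) + 1
            key = (ti, tj)
            if key not in h:
                h[key] = [[0] * n_phi for _ in range(n_theta)]
            h[key][tb][pb] += 1
            n_contacts += 1
    energies = {}
    for ti in AA20:
        for tj in AA20:
            key = (ti, tj)
            table = [[missing_pair_energy] * n_phi for _ in range(n_theta)]
            if key in n_ij and n_ij[key] > 0:
                p_i = n_i[ti] / n_res_total
                p_j = n_i[tj] / n_res_total
                p_ij = n_ij[key] / n_contacts
                for tb in range(n_theta):
                    w = bf_solid_angle(tb, n_theta, n_phi)
                    for pb in range(n_phi):
                        p_bin = (h[key][tb][pb] + alpha) / (n_ij[key] + alpha * B)
                        table[tb][pb] = -math.log((p_ij / (p_i * p_j)) * p_bin / w)
            energies[key] = table
    return energies


def bf_score(chain, energies, n_theta=20, n_phi=20, mode="fixed", r_fixed=6.0,
             radii=None, include_adjacent=True):
    total = 0.0
    for (ti, tj, _si, _sj, sph) in bf_contacts(chain, mode, r_fixed, radii, include_adjacent):
        tb, pb = bf_bin(sph[1], sph[2], n_theta, n_phi)
        total += energies[(ti, tj)][tb][pb]
    return total
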