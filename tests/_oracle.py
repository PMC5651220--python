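"""Independent brute-force oracle: exhaustive double-loop interaction counting.

Deliberately avoids the package's spatial-index path: plain Python loops,
math-module geometry, its own donor/acceptor logic. Used to verify that the
k-d-tree implementation is exactly equivalent.
"""

import math


def _dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def oracle_pose_record(pose, receptor, params):
    """Per-residue (contacts, clashes, hbonds, clashing) via exhaustive loops.

    Returns (contacts: dict, clashes: dict, hbonds: dict, clashing: set)
    keyed by ResidueKey.
    """
    contacts, clashes, hbonds, clashing = {}, {}, {}, set()
    lig = [a for a in pose.atoms
           if params.include_hydrogens_in_contacts or not a.is_hydrogen]
    rec = [a for a in receptor.atoms
           if params.include_hydrogens_in_contacts or not a.is_hydrogen]
    for la in lig:
        for ra in rec:
            d = _dist(la.coords, ra.coords)
            overlap = la.vdw_radius + ra.vdw_radius - d
            key = ra.residue_key
            if overlap >= params.clash_cutoff:
                clashes[key] = clashes.get(key, 0) + 1
                clashing.add(key)
                if params.clash_also_contact:
                    contacts[key] = contacts.get(key, 0) + 1
            elif overlap >= params.contact_cutoff:
                contacts[key] = contacts.get(key, 0) + 1
    for donor, acceptor, rec_key in oracle_hbonds(pose, receptor, params):
        hbonds[rec_key] = hbonds.get(rec_key, 0) + 1
    return contacts, clashes, hbonds, clashing


def _bonded_hydrogens(heavy, atoms):
    out = []
    for a in atoms:
        if not a.is_hydrogen:
            continue
        if heavy.residue_key is not None and a.residue_key != heavy.residue_key:
            continue
        if _dist(heavy.coords, a.coords) <= 1.25:
            out.append(a)
    return out


def _angle_deg(apex, p1, p2):
    v1 = [a - b for a, b in zip(p1, apex)]
    v2 = [a - b for a, b in zip(p2, apex)]
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    if n1 == 0 or n2 == 0:
        return 0.0
    c = sum(a * b for a, b in zip(v1, v2)) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def oracle_hbonds(pose, receptor, params):
    """All accepted donor→acceptor pairs as (donor, acceptor, receptor_residue)."""
    lig_polar = [a for a in pose.atoms if a.element.upper() in ("N", "O")]
    rec_polar = [a for a in receptor.atoms if a.element.upper() in ("N", "O")]
    lig_has_h = any(a.is_hydrogen for a in pose.atoms)
    rec_has_h = any(a.is_hydrogen for a in receptor.atoms)
    found = []

    def check(donor, acceptor, donor_atoms, donor_mol_has_h, rec_key, d):
        hs = _bonded_hydrogens(donor, donor_atoms)
        if hs:
            if min(_angle_deg(donor.coords, h.coords, acceptor.coords)
                   for h in hs) <= params.hbond_angle_max:
                found.append((donor, acceptor, rec_key))
        elif not donor_mol_has_h:
            found.append((donor, acceptor, rec_key))

    for la in lig_polar:
        for ra in rec_polar:
            d = _dist(la.coords, ra.coords)
            if d > params.hbond_da_max:
                continue
            check(la, ra, pose.atoms, lig_has_h, ra.residue_key, d)
            check(ra, la, receptor.atoms, rec_has_h, ra.residue_key, d)
    return found


def oracle_score_pipeline(ensembles, receptor, params, thresholds, log_base="natural"):
    """Independent end-to-end scoring: oracle records, inline tiering and
    log arithmetic. Returns {residue_key: final_score} with presence >= 2
    semantics left to the caller."""
    log = math.log10 if log_base == "10" else math.log
    per_experiment = []
    for ens in ensembles:
        records = {p.index: oracle_pose_record(p, receptor, params)
                   for p in ens.poses}
        tier_terms = {}
        for thr in thresholds:
            subset = [p for p in ens.poses if p.binding_energy < thr]
            totals = {}
            for p in subset:
                c, cl, hb, clashing = records[p.index]
                for key in set(c) | set(cl) | set(hb):
                    t = totals.setdefault(key, [0, 0, 0, 0])
                    t[0] += c.get(key, 0)
                    t[1] += cl.get(key, 0)
                    t[2] += hb.get(key, 0)
                    t[3] += 1 if key in clashing else 0
            for key, (nco, ncl, nh, ccl) in totals.items():
                if nco - ncl > 0 and nh > 0 and ccl > 0:
                    term = log(nco - ncl) - log(nh / ccl)
                    tier_terms.setdefault(key, []).append(term)
                else:
                    tier_terms.setdefault(key, [])
        per_experiment.append(
            {key: sum(terms) for key, terms in tier_terms.items() if terms}
        )
    finals, presence = {}, {}
    for smap in per_experiment:
        for key, score in smap.items():
            finals[key] = finals.get(key, 0.0) + score
            presence[key] = presence.get(key, 0) + 1
    return finals, presence
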