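"""Brute-force oracle counters used by the acceptance script.

Straightforward O(N^2) enumerations of the contact and hydrogen-bond
definitions, independent of the package's accelerated implementations.
"""

import numpy as np

from structmat import observables as obs

def brute_force_contacts(frame, peptide_chain, receptor_chains,
                         core_resnums, cutoff=4.0):
    """O(N^2) all-pairs oracle with the same inclusive <= rule."""
    rec = [a for a in frame.atoms
           if a.chain_id in receptor_chains and a.element != "H"]
    out = np.zeros(len(core_resnums), dtype=int)
    for k, rn in enumerate(core_resnums):
        pep = [a for a in frame.atoms
               if a.chain_id == peptide_chain and a.residue_number == rn
               and a.element != "H"]
        for pa in pep:
            for ra in rec:
                if np.sqrt(((pa.position - ra.position) ** 2).sum()) <= cutoff:
                    out[k] += 1
    return out


def brute_force_hbonds(frame, peptide_chain, receptor_chains, core_resnums,
                       criteria=None):
    """Independent enumeration of every peptide-backbone donor/acceptor pair.

    Applies the same chemistry rules as the package (placed amide H,
    distance-only fallback for unplaceable donors) with independent geometry
    code.
    """
    crit = criteria or obs.HBondCriteria()

    def residues_of(chain):
        res = {}
        order = []
        for a in frame.atoms:
            if a.chain_id == chain:
                res.setdefault(a.residue_number, {})[a.atom_name] = a
                if a.residue_number not in order:
                    order.append(a.residue_number)
        return res, order

    def angle(a, b, c):
        u, v = a - b, c - b
        cosang = np.dot(u, v) / np.sqrt(np.dot(u, u) * np.dot(v, v))
        return np.degrees(np.arccos(max(-1.0, min(1.0, cosang))))

    def hydrogens_for(chain, rn, donor, res, order):
        hs = [a.position for a in frame.atoms
              if a.element == "H" and a.chain_id == chain
              and a.residue_number == rn
              and np.linalg.norm(a.position - donor.position) <= 1.2]
        if hs:
            return hs
        if donor.atom_name == "N":
            if donor.residue_name == "PRO" or order.index(rn) == 0:
                return []
            prev = res[order[order.index(rn) - 1]]
            ca = res[rn].get("CA")
            if ca is None or "C" not in prev:
                return None
            u1 = prev["C"].position - donor.position
            u2 = ca.position - donor.position
            u1, u2 = u1 / np.linalg.norm(u1), u2 / np.linalg.norm(u2)
            b = u1 + u2
            return [donor.position - b / np.linalg.norm(b)]
        return None

    def bond_ok(donor, hs, acc):
        if np.linalg.norm(acc.position - donor.position) > crit.d_a_max:
            return False
        if hs is None:
            return True
        for h in hs:
            if (np.linalg.norm(acc.position - h) <= crit.h_a_max
                    and angle(donor.position, h, acc.position)
                    >= crit.theta_min_deg):
                return True
        return False

    pep_res, pep_order = residues_of(peptide_chain)
    out = np.zeros(len(core_resnums), dtype=int)
    for k, rn in enumerate(core_resnums):
        atoms = pep_res.get(rn, {})
        if not {"N", "CA", "C", "O"} <= set(atoms):
            continue
        n = 0
        hs = hydrogens_for(peptide_chain, rn, atoms["N"], pep_res, pep_order)
        if hs:
            for c in receptor_chains:
                res, order = residues_of(c)
                for rrn, ratoms in res.items():
                    for a in ratoms.values():
                        if a.element == "O" or (
                                a.residue_name == "HIS"
                                and a.atom_name in ("ND1", "NE2")):
                            if bond_ok(atoms["N"], hs, a):
                                n += 1
        for c in receptor_chains:
            res, order = residues_of(c)
            for rrn, ratoms in res.items():
                for a in ratoms.values():
                    is_donor = a.atom_name == "N" or a.atom_name in \
                        obs.SIDECHAIN_DONORS.get(a.residue_name, ())
                    if not is_donor or a.element == "H":
                        continue
                    dhs = hydrogens_for(c, rrn, a, res, order)
                    if dhs == []:
                        continue
                    if bond_ok(a, dhs, atoms["O"]):
                        n += 1
        out[k] = n
    return out
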