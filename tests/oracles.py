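"""Independent brute-force oracles for the energy and sampling pipeline.

Everything here is deliberately written straight-line, with its own literal
class partition and pair-energy table, sharing no code with the package
implementation it cross-checks.
"""

import itertools
import math

import numpy as np

ORACLE_CLASS = {}
for _cls, _members in [
    ("pos", "KRH"), ("neg", "DE"), ("pol", "STNQYC"),
    ("hyd", "AVLIMFW"), ("spe", "GP"),
]:
    for _aa in _members:
        ORACLE_CLASS[_aa] = _cls

ORACLE_TABLE = {
    frozenset(["pos", "neg"]): -2.0,
    frozenset(["pos"]): 2.0,
    frozenset(["neg"]): 2.0,
    frozenset(["hyd"]): -1.0,
    frozenset(["pol"]): -0.5,
    frozenset(["pol", "pos"]): -0.5,
    frozenset(["pol", "neg"]): -0.5,
    frozenset(["hyd", "pos"]): 0.5,
    frozenset(["hyd", "neg"]): 0.5,
}


def oracle_pair(aa1, aa2, dist, contact_cutoff=8.0, clash_cutoff=3.0, clash_penalty=10.0):
    if aa1 == "X" or aa2 == "X":
        return 0.0
    if dist > contact_cutoff:
        return 0.0
    e = ORACLE_TABLE.get(frozenset([ORACLE_CLASS[aa1], ORACLE_CLASS[aa2]]), 0.0)
    if dist < clash_cutoff:
        e += clash_penalty
    return e


def oracle_centers(template, cb_truth):
    """Centers from generator ground truth: true CB, or CA for glycine."""
    centers = {}
    for prefix, chain in (("G", template.groove), ("P", template.peptide)):
        for res in chain.residues:
            key_truth = f"{chain.chain_id}:{res.seq_id}"
            if res.aa == "G":
                centers[f"{prefix}{res.seq_id}"] = res.atom("CA").coords
            elif key_truth in cb_truth:
                centers[f"{prefix}{res.seq_id}"] = cb_truth[key_truth]
            else:
                centers[f"{prefix}{res.seq_id}"] = res.atom("CB").coords
    return centers


def oracle_bind_energy(centers, groove_seq, pep_seq, intra=False, min_sep=3):
    """Naive double loop over all center pairs."""
    e_bind = 0.0
    for i, p_aa in enumerate(pep_seq, start=1):
        for j, g_aa in enumerate(groove_seq, start=1):
            d = float(np.linalg.norm(centers[f"P{i}"] - centers[f"G{j}"]))
            e_bind += oracle_pair(p_aa, g_aa, d)
    if not intra:
        return e_bind
    e_total = e_bind
    for prefix, seq in (("G", groove_seq), ("P", pep_seq)):
        for i in range(1, len(seq) + 1):
            for j in range(i + min_sep, len(seq) + 1):
                d = float(np.linalg.norm(centers[f"{prefix}{i}"] - centers[f"{prefix}{j}"]))
                e_total += oracle_pair(seq[i - 1], seq[j - 1], d)
    return e_total


def oracle_enumerate_rank_enrich(centers, base_groove_seq, subs, pep_seq, top_fraction):
    """Straight-line enumerate -> score -> sort -> count, for N <= 4.

    ``subs`` is a list of (thread_position, to_aa, report_position) triples.
    Returns (ranked list of (mask_int, E_bind), enrichment dict).
    """
    n = len(subs)
    assert n <= 4
    scored = []
    for bits in itertools.product([0, 1], repeat=n):
        mask_int = sum(b << i for i, b in enumerate(bits))
        seq = list(base_groove_seq)
        for b, (tpos, to_aa, _) in zip(bits, subs):
            if b:
                seq[tpos - 1] = to_aa
        e = oracle_bind_energy(centers, "".join(seq), pep_seq)
        scored.append((mask_int, e))
    scored.sort(key=lambda x: (x[1], x[0]))
    pool_size = max(1, math.ceil(top_fraction * len(scored)))
    pool = scored[:pool_size]
    enr = {}
    for i, (_, _, rpos) in enumerate(subs):
        enr[rpos] = sum(1 for m, _ in pool if (m >> i) & 1) / pool_size
    return scored, enr
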