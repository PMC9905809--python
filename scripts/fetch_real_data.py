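#!/usr/bin/env python
"""Fetch the deposited structures used by the optional real-data checks.

Downloads pMHC-I entries from the PDB (1Q94, 5VGE, 4QRT, 5HHN, 8ERX, 8ESH),
normalizes each to chain A = heavy chain / chain C = peptide, and extracts
mature heavy-chain allele sequences (A*11:01 from 1Q94, C*07:02 from 5VGE,
A*02:01 from 5HHN) into an alleles FASTA.  Results land in
``scratch/real_data/``, which enables the two download-dependent tests in
tests/test_acceptance.py.  Requires network access; everything else in the
package runs fully offline on synthetic fixtures.

    python scripts/fetch_real_data.py [--out-dir scratch/real_data]
"""

import argparse
import re
import urllib.request
from pathlib import Path

import gemmi

ENTRIES = {
    "1q94": "A*11:01",   # A*11:01 / HIV-1 RT template
    "5vge": "C*07:02",   # C*07:02 / RYR template
    "4qrt": None,        # B*08:01 / CMV wild-type (RMSD reference)
    "5hhn": "A*02:01",   # A*02:01 (sequence source)
    "8erx": None,        # A*11:01-A*02:01 chimera / HIV-1 RT
    "8esh": None,        # B*08:01-A*02:01 chimera / CMV
}

MATURE_START = re.compile(r"[GC]SHSM")


def fetch(pdb_id: str, dest: Path) -> Path:
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    raw = dest / f"{pdb_id}_raw.pdb"
    if not raw.exists():
        print(f"downloading {url}")
        urllib.request.urlretrieve(url, raw)
    return raw


def chain_sequence(chain: gemmi.Chain) -> str:
    seq = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and info.is_amino_acid():
            seq.append(gemmi.find_tabulated_residue(res.name).one_letter_code.upper())
    return "".join(seq)


def normalize(raw: Path, out: Path) -> tuple[str, str]:
    """Rewrite with chain A = heavy (longest protein chain), C = peptide
    (shortest chain of 8-15 residues); returns the heavy-chain sequence."""
    st = gemmi.read_structure(str(raw))
    st.setup_entities()
    st.remove_ligands_and_waters()
    model = st[0]
    lengths = {ch.name: len(chain_sequence(ch)) for ch in model}
    heavy = max(lengths, key=lengths.get)
    peptide_candidates = {n: l for n, l in lengths.items() if 8 <= l <= 15}
    if not peptide_candidates:
        raise SystemExit(f"{raw}: no 8-15-mer peptide chain found ({lengths})")
    peptide = min(peptide_candidates, key=peptide_candidates.get)

    new = gemmi.Structure()
    new.name = st.name
    nm = gemmi.Model("1")
    for src_name, dst_name in ((heavy, "A"), (peptide, "C")):
        ch = model[src_name].clone()
        ch.name = dst_name
        nm.add_chain(ch)
    new.add_model(nm)
    new.setup_entities()
    new.write_pdb(str(out))
    return chain_sequence(model[heavy]), chain_sequence(model[peptide])


def mature(seq: str) -> str:
    m = MATURE_START.search(seq[:40])
    if m:
        return seq[m.start():]
    print("  warning: mature-start motif not found; keeping sequence as-is")
    return seq


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path,
                        default=Path(__file__).resolve().parent.parent / "scratch" / "real_data")
    args = parser.parse_args()
    out_dir = args.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    alleles: dict[str, str] = {}
    for pdb_id, allele in ENTRIES.items():
        raw = fetch(pdb_id, out_dir)
        heavy_seq, pep_seq = normalize(raw, out_dir / f"{pdb_id}.pdb")
        print(f"{pdb_id}: heavy {len(heavy_seq)} aa, peptide {pep_seq}")
        if allele:
            alleles[allele] = mature(heavy_seq)

    with open(out_dir / "alleles.fasta", "w") as fh:
        for name, seq in alleles.items():
            fh.write(f">{name}\n{seq}\n")
    print(f"wrote {out_dir / 'alleles.fasta'} ({', '.join(alleles)})")


if __name__ == "__main__":
    main()
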