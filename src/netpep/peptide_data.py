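"""Reference peptide panel: kinase/transcription-factor substrate peptides
from published protein-peptide complex structures.

These are the peptide chains of complexes whose receptors are the AKT
kinases, transcription factor E2F1 and endothelial nitric-oxide synthase
(NOS3) — a compact, real panel used both as documentation examples and
as seed data by the fixture generator.  X marks a non-standard residue
in the deposited chain.
"""

from __future__ import annotations

from .peptides import PeptideRecord

__all__ = ["REFERENCE_PEPTIDES", "reference_records"]

# (pdb_id, chain, sequence, description, receptor gene)
REFERENCE_PEPTIDES: list[tuple[str, str, str, str, str]] = [
    ("6buu", "F", "GRPRTTXFAEX", "GLY-ARG-PRO-ARG-THR-THR-ZXW-PHE-ALA-GLU", "AKT1"),
    ("6buu", "G", "GRPRTTXFAEX", "GLY-ARG-PRO-ARG-THR-THR-ZXW-PHE-ALA-GLU", "AKT1"),
    ("6npz", "F", "GRPRTTXFAEX", "Bisubstrate", "AKT1"),
    ("6npz", "G", "GRPRTTXFAEX", "Bisubstrate", "AKT1"),
    ("2jdo", "C", "GRPRTTSFAE", "Glycogen synthase kinase-3 beta", "AKT2"),
    ("2jdr", "C", "GRPRTTSFAE", "Glycogen synthase kinase-3 beta", "AKT2"),
    ("2uw9", "C", "GRPRTTSFAE", "Glycogen synthase kinase-3 beta", "AKT2"),
    ("3e87", "C", "GRPRTTSFAE", "Glycogen synthase kinase-3 beta peptide", "AKT2"),
    ("3e87", "D", "GRPRTTSFAE", "Glycogen synthase kinase-3 beta peptide", "AKT2"),
    ("3e88", "C", "GRPRTTSFAE", "Glycogen synthase kinase-3 beta peptide", "AKT2"),
    ("3e88", "D", "GRPRTTSFAE", "Glycogen synthase kinase-3 beta peptide", "AKT2"),
    ("6g0p", "B", "PGXGVXSPG", "Transcription factor E2F1", "E2F1"),
    ("2ll7", "B", "KKTFKEVANAVKISASL", "Nitric oxide synthase, endothelial", "NOS3"),
]


def reference_records() -> list[PeptideRecord]:
    """The reference panel as validated records with computed properties."""
    return [
        PeptideRecord(pdb_id=p, chain=c, sequence=s, description=d, receptor=r)
        for p, c, s, d, r in REFERENCE_PEPTIDES
    ]
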