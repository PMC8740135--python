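"""Peptide physicochemical profiling, clustering, and consensus sequences.

Properties follow the ProtParam conventions: average residue masses plus
one water for the molecular weight, the F/W/Y fraction for aromaticity
(unknown residues X stay in the denominator), the Guruprasad dipeptide
weight (DIWV) statistic for the instability index, and a bisection
solve of the Bjellqvist charge model for the isoelectric point.  A
sequence containing the unknown residue X has no defined molecular
weight, and any dipeptide containing X makes the instability index
undefined; X carries no charge, so the pI is still defined.

Clustering is a deterministic greedy profile method: peptides are
processed longest-first, each either joins the best existing cluster
whose consensus it matches at >= ``min_identity`` gapless best-offset
identity (X matches nothing) or seeds a new cluster, and one refinement
pass re-assigns every peptide against the final consensi.  The cluster
consensus aligns members gaplessly at their best offsets to the longest
member and takes the per-position majority over positions covered by at
least half the members, recording the full position-frequency matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import ProtParamData, molecular_weight as _bio_mw
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideRecord",
    "PeptideCluster",
    "molecular_weight",
    "aromaticity",
    "instability_index",
    "isoelectric_point",
    "cluster_peptides",
    "consensus",
    "read_peptide_table",
    "read_fasta",
    "write_fasta",
    "records_to_frame",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
VALID_AA = STANDARD_AA | {"X"}
NONSTANDARD = set("XBZUO")
ALPHABET = sorted(STANDARD_AA) + ["X"]  # PFM column order


def _check(seq: str, who: str = "sequence") -> str:
    seq = seq.strip().upper()
    if not seq:
        raise ValueError(f"{who}: empty sequence")
    bad = set(seq) - VALID_AA
    if bad:
        raise ValueError(f"{who}: invalid residue letter(s) {sorted(bad)}")
    return seq


def molecular_weight(seq: str, monoisotopic: bool = False) -> float | None:
    """Average-mass molecular weight in Da, or None if X is present."""
    seq = _check(seq)
    if set(seq) & NONSTANDARD:
        return None
    return float(_bio_mw(seq, seq_type="protein", monoisotopic=monoisotopic))


def aromaticity(seq: str) -> float:
    """Fraction of aromatic residues (F, W, Y); X counts in the denominator."""
    seq = _check(seq)
    return sum(seq.count(a) for a in "FWY") / len(seq)


def instability_index(seq: str) -> float | None:
    """Guruprasad instability index, or None if any dipeptide contains X."""
    seq = _check(seq)
    if len(seq) < 2:
        raise ValueError("instability index needs length >= 2")
    if set(seq) & NONSTANDARD:
        return None
    diwv = ProtParamData.DIWV
    total = sum(diwv[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return 10.0 / len(seq) * total


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH of zero net charge by bisection on the Bjellqvist charge model.

    X contributes no charge; termini pKa follow the terminal residues.
    """
    seq = _check(seq)
    ip = IsoelectricPoint(seq)
    lo, hi = 0.0, 14.0
    # net charge is monotone decreasing in pH
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = ip.charge_at_pH(mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass
class PeptideRecord:
    """One peptide chain from a protein-peptide complex, with its properties."""

    pdb_id: str
    chain: str
    sequence: str
    description: str = ""
    receptor: str = ""
    mol_weight: float | None = field(init=False)
    aromaticity: float = field(init=False)
    instability: float | None = field(init=False)
    isoelectric_point: float = field(init=False)

    def __post_init__(self) -> None:
        self.sequence = _check(self.sequence, f"{self.pdb_id}_{self.chain}")
        self.receptor = self.receptor.strip().upper()
        self.mol_weight = molecular_weight(self.sequence)
        self.aromaticity = aromaticity(self.sequence)
        self.instability = instability_index(self.sequence) if len(self.sequence) >= 2 else None
        self.isoelectric_point = isoelectric_point(self.sequence)

    @property
    def size(self) -> int:
        return len(self.sequence)

    @property
    def label(self) -> str:
        return f"{self.pdb_id}_{self.chain}"


@dataclass
class PeptideCluster:
    cluster_id: int
    members: list[PeptideRecord]
    consensus: str = ""
    pfm: pd.DataFrame | None = None  # rows = alignment positions, columns = ALPHABET


# ----------------------------------------------------------------------
# gapless best-offset identity and consensus
# ----------------------------------------------------------------------

def best_offset_identity(a: str, b: str) -> tuple[float, int]:
    """Best gapless identity sliding the shorter fully along the longer.

    Identity = matching positions / length of the shorter sequence, with
    X matching nothing.  Returns (identity, offset of the shorter within
    the longer).
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best, best_off = -1.0, 0
    for off in range(len(long_) - len(short) + 1):
        m = sum(
            1
            for i, c in enumerate(short)
            if c != "X" and c == long_[off + i]
        )
        ident = m / len(short)
        if ident > best:
            best, best_off = ident, off
    return best, best_off


def consensus(members: list[PeptideRecord]) -> tuple[str, pd.DataFrame]:
    """Majority consensus and position-frequency matrix of a cluster.

    Members align gaplessly at their best offsets to the longest member;
    the consensus covers positions seen by >= 50% of members, taking the
    argmax residue (ties broken toward the alphabetically smallest,
    logged).
    """
    if not members:
        raise ValueError("empty cluster")
    ref = max(members, key=lambda r: (r.size, r.sequence))
    width = ref.size
    counts = np.zeros((width, len(ALPHABET)), dtype=int)
    cover = np.zeros(width, dtype=int)
    col = {c: i for i, c in enumerate(ALPHABET)}
    for rec in members:
        _, off = best_offset_identity(rec.sequence, ref.sequence)
        for i, c in enumerate(rec.sequence):
            counts[off + i, col[c]] += 1
            cover[off + i] += 1
    pfm = pd.DataFrame(counts, columns=ALPHABET)
    pfm.index.name = "position"
    letters = []
    for pos in range(width):
        if cover[pos] * 2 < len(members):
            continue
        row = counts[pos]
        best = row.max()
        winners = [ALPHABET[i] for i in range(len(ALPHABET)) if row[i] == best]
        if len(winners) > 1:
            logger.info("consensus tie at position %d: %s -> %s", pos, winners, winners[0])
        letters.append(winners[0])
    return "".join(letters), pfm


def cluster_peptides(
    records: list[PeptideRecord],
    min_identity: float = 0.7,
    min_cluster: int = 1,
    seed: int = 0,
) -> list[PeptideCluster]:
    """Deterministic greedy profile clustering of peptide sequences.

    ``seed`` is accepted for interface uniformity; the algorithm is
    deterministic and does not consume randomness.
    """
    if not records:
        raise ValueError("no peptide records")
    if not 0.0 < min_identity <= 1.0:
        raise ValueError("min_identity must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-r.size, r.sequence, r.label))
    clusters: list[list[PeptideRecord]] = []
    consensi: list[str] = []
    for rec in ordered:
        best_i, best_ident = -1, min_identity
        for i, cons in enumerate(consensi):
            ident, _ = best_offset_identity(rec.sequence, cons)
            if ident > best_ident or (ident == best_ident and best_i == -1):
                best_i, best_ident = i, ident
        if best_i >= 0:
            clusters[best_i].append(rec)
            consensi[best_i] = consensus(clusters[best_i])[0]
        else:
            clusters.append([rec])
            consensi.append(rec.sequence)
    # refinement pass against the final consensi
    final_cons = list(consensi)
    refined: list[list[PeptideRecord]] = [[] for _ in clusters]
    for rec in ordered:
        best_i, best_ident = -1, min_identity
        for i, cons in enumerate(final_cons):
            ident, _ = best_offset_identity(rec.sequence, cons)
            if ident > best_ident or (ident == best_ident and best_i == -1):
                best_i, best_ident = i, ident
        if best_i < 0:  # keep its original home if it no longer matches anything
            best_i = next(i for i, c in enumerate(clusters) if rec in c)
        refined[best_i].append(rec)
    out: list[PeptideCluster] = []
    cid = 0
    for group in refined:
        if len(group) < max(min_cluster, 1) or not group:
            continue
        cons, pfm = consensus(group)
        out.append(PeptideCluster(cid, group, cons, pfm))
        cid += 1
    return out


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """TSV with header columns pdb_id, chain, sequence, description[, receptor]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"pdb_id", "chain", "sequence", "description"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        PeptideRecord(
            pdb_id=row.pdb_id,
            chain=row.chain,
            sequence=row.sequence,
            description=row.description,
            receptor=getattr(row, "receptor", ""),
        )
        for row in df.itertuples()
    ]


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """FASTA with ``>pdbid_chain description`` headers."""
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        pdb_id, _, chain = sr.id.partition("_")
        records.append(
            PeptideRecord(
                pdb_id=pdb_id,
                chain=chain or "A",
                sequence=str(sr.seq),
                description=sr.description.partition(" ")[2],
            )
        )
    return records


def write_fasta(records: list[PeptideRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.label, description=r.description) for r in records],
        str(path),
        "fasta",
    )


def records_to_frame(records: list[PeptideRecord]) -> pd.DataFrame:
    """Property table with '-' markers for undefined values."""
    rows = []
    for r in records:
        rows.append(
            {
                "pdb_id": r.pdb_id,
                "chain": r.chain,
                "size": r.size,
                "sequence": r.sequence,
                "description": r.description,
                "receptor": r.receptor,
                "mol_weight": "-" if r.mol_weight is None else round(r.mol_weight, 2),
                "aromaticity": round(r.aromaticity, 2),
                "instability": "-" if r.instability is None else round(r.instability, 2),
                "isoelectric_point": round(r.isoelectric_point, 2),
            }
        )
    return pd.DataFrame(rows)
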