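"""Peptide properties, clustering, consensus, and I/O."""

import numpy as np
import pytest

from netpep.peptide_data import REFERENCE_PEPTIDES, reference_records
from netpep.peptides import (
    PeptideRecord,
    aromaticity,
    best_offset_identity,
    cluster_peptides,
    consensus,
    instability_index,
    isoelectric_point,
    molecular_weight,
    read_fasta,
    read_peptide_table,
    write_fasta,
)
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint


class TestProperties:
    def test_unknown_residue_blocks_mw_and_instability(self):
        assert molecular_weight("GRPRTTXFAEX") is None
        assert instability_index("GRPRTTXFAEX") is None

    def test_aromaticity_counts_x_in_denominator(self):
        assert aromaticity("GRPRTTXFAEX") == pytest.approx(1 / 11)
        assert aromaticity("AAAA") == 0.0
        assert aromaticity("FWY") == 1.0

    def test_mw_increases_under_appending(self):
        seq = "GRPRT"
        for extra in "ACDE":
            assert molecular_weight(seq + extra) > molecular_weight(seq)

    def test_pi_has_zero_net_charge(self):
        for seq in ("GRPRTTSFAE", "KKTFKEVANAVKISASL", "DDEEK"):
            ph = isoelectric_point(seq)
            assert abs(IsoelectricPoint(seq).charge_at_pH(ph)) < 1e-4

    def test_x_is_uncharged_for_pi(self):
        assert isoelectric_point("GRPRTTXFAEX") == pytest.approx(
            isoelectric_point("GRPRTTSFAE"), abs=0.15
        )

    def test_invalid_letters_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            molecular_weight("GRPR1TSFAE")
        with pytest.raises(ValueError, match="empty"):
            aromaticity("")
        with pytest.raises(ValueError, match="length"):
            instability_index("A")

    def test_monoisotopic_mass_is_smaller(self):
        assert molecular_weight("GRPRTTSFAE", monoisotopic=True) < molecular_weight("GRPRTTSFAE")


class TestIdentityAndConsensus:
    def test_best_offset_identity_slides_shorter(self):
        ident, off = best_offset_identity("GRPRTTSFAE", "GRPRTTXFAEX")
        assert ident == pytest.approx(0.9) and off == 0

    def test_x_matches_nothing(self):
        ident, _ = best_offset_identity("XXXX", "XXXX")
        assert ident == 0.0

    def test_single_member_consensus_is_member(self):
        rec = PeptideRecord("1abc", "A", "GRPRTTSFAE")
        cons, pfm = consensus([rec])
        assert cons == "GRPRTTSFAE"
        assert pfm.to_numpy().sum(axis=1).tolist() == [1] * 10

    def test_family_consensus_majority_and_coverage(self):
        fam = [PeptideRecord(p, c, s) for p, c, s, _, _ in REFERENCE_PEPTIDES if s.startswith("GRPRTT")]
        cons, pfm = consensus(fam)
        # 7 S-variants outvote 4 X-variants at position 7; the final X-only
        # column (4/11 members) falls below 50% coverage and is dropped
        assert cons == "GRPRTTSFAE"
        assert pfm.loc[6, "S"] == 7 and pfm.loc[6, "X"] == 4
        assert pfm.to_numpy()[0].sum() == len(fam)

    def test_tie_breaks_lexicographic(self):
        recs = [PeptideRecord("1a", "A", "AC"), PeptideRecord("1b", "A", "AD")]
        cons, _ = consensus(recs)
        assert cons == "AC"


class TestClustering:
    def test_reference_panel_clusters(self):
        clusters = cluster_peptides(reference_records(), min_identity=0.7)
        by_seq = {}
        for c in clusters:
            for m in c.members:
                by_seq.setdefault(c.cluster_id, set()).add(m.sequence)
        family = [c for c in clusters if any(s.startswith("GRPRTT") for s in by_seq[c.cluster_id])]
        assert len(family) == 1 and len(family[0].members) == 11
        singles = [c for c in clusters if len(c.members) == 1]
        assert {c.members[0].sequence for c in singles} == {"PGXGVXSPG", "KKTFKEVANAVKISASL"}

    def test_identical_sequences_one_cluster(self):
        recs = [PeptideRecord(f"1a{i}", "A", "GRPRTTSFAE") for i in range(4)]
        assert len(cluster_peptides(recs)) == 1

    def test_full_identity_gives_singletons(self):
        recs = [PeptideRecord("1a", "A", "GRPRTTSFAE"), PeptideRecord("1b", "A", "KKTFKEVANAV")]
        assert len(cluster_peptides(recs, min_identity=1.0)) == 2

    def test_order_invariance_after_refinement(self):
        recs = reference_records()
        base = cluster_peptides(recs, min_identity=0.7)
        sig = sorted(tuple(sorted(m.label for m in c.members)) for c in base)
        rng = np.random.default_rng(5)
        for _ in range(5):
            shuffled = [recs[i] for i in rng.permutation(len(recs))]
            got = cluster_peptides(shuffled, min_identity=0.7)
            assert sorted(tuple(sorted(m.label for m in c.members)) for c in got) == sig

    def test_min_cluster_filters_singletons(self):
        clusters = cluster_peptides(reference_records(), min_identity=0.7, min_cluster=2)
        assert all(len(c.members) >= 2 for c in clusters)


class TestIO:
    def test_read_table_and_fasta_roundtrip(self, tmp_path):
        rows = ["pdb_id\tchain\tsequence\tdescription\treceptor"]
        rows += ["\t".join(r) for r in (("1abc", "A", "grprttsfae", "demo", "AKT1"),)]
        p = tmp_path / "pep.tsv"
        p.write_text("\n".join(rows) + "\n")
        recs = read_peptide_table(p)
        assert recs[0].sequence == "GRPRTTSFAE"  # uppercased
        assert recs[0].receptor == "AKT1"
        fa = tmp_path / "pep.fasta"
        write_fasta(recs, fa)
        back = read_fasta(fa)
        assert back[0].sequence == recs[0].sequence and back[0].pdb_id == "1abc"

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "pep.tsv"
        p.write_text("pdb_id\tchain\tsequence\n1abc\tA\tGRPR\n")
        with pytest.raises(ValueError, match="description"):
            read_peptide_table(p)

    def test_invalid_residue_names_record(self, tmp_path):
        p = tmp_path / "pep.tsv"
        p.write_text("pdb_id\tchain\tsequence\tdescription\n1abc\tA\tGRPJ\tbad\n")
        with pytest.raises(ValueError, match="1abc_A"):
            read_peptide_table(p)
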