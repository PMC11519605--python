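"""Combinatorial variant peptide database construction."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cysvarforge.dbforge import (
    ForgeConfig,
    WindowCluster,
    apply_variants,
    count_combinations,
    dedup_and_write,
    enumerate_combinations,
    forge_protein,
    generate_decoys,
    group_windows,
    reference_peptide_set,
    single_each_fallback,
)
from cysvarforge.missense import MissenseVariant
from cysvarforge.proteolysis import digest, monoisotopic_mass


def mv(idx, ref, alt, acc="P1", source="RNA"):
    return MissenseVariant(
        protein_accession=acc, residue_index=idx, ref_aa=ref, alt_aa=alt,
        sources=frozenset({source}),
    )


class TestGroupWindows:
    def test_single_variant_single_cluster(self):
        [c] = group_windows([mv(10, "A", "G")])
        assert c.n == 1

    def test_pairwise_distance_chaining(self):
        clusters = group_windows(
            [mv(10, "A", "G"), mv(35, "A", "G"), mv(80, "A", "G")], window_size=30
        )
        assert [tuple(v.residue_index for v in c.variants) for c in clusters] == [
            (10, 35), (80,)
        ]

    def test_same_site_alleles_share_cluster(self):
        [c] = group_windows([mv(12, "A", "G"), mv(12, "A", "T")])
        assert c.n == 2
        assert len(c.same_site_groups()) == 1

    def test_mixed_proteins_rejected(self):
        with pytest.raises(ValueError):
            group_windows([mv(1, "A", "G", acc="P1"), mv(2, "A", "G", acc="P2")])


def brute_force_subsets(variants):
    """Oracle: all nonempty subsets without two same-site members."""
    out = set()
    for r in range(1, len(variants) + 1):
        for combo in itertools.combinations(variants, r):
            sites = [v.residue_index for v in combo]
            if len(set(sites)) == len(sites):
                out.add(frozenset(combo))
    return out


@pytest.mark.parametrize("n", [1, 2, 3, 5, 8, 12])
def test_combination_count_law_distinct_sites(n):
    cluster = WindowCluster("P1", tuple(mv(i + 1, "A", "G") for i in range(n)))
    subsets = {frozenset(s) for s in enumerate_combinations(cluster)}
    assert subsets == brute_force_subsets(list(cluster.variants))
    assert len(subsets) == 2**n - 1 == count_combinations(cluster)


def test_combination_count_same_site_exclusion():
    variants = (mv(5, "A", "G"), mv(5, "A", "T"), mv(9, "R", "C"))
    cluster = WindowCluster("P1", variants)
    subsets = {frozenset(s) for s in enumerate_combinations(cluster)}
    assert subsets == brute_force_subsets(list(variants))
    assert count_combinations(cluster) == (2 + 1) * (1 + 1) - 1 == 5


def test_billion_scale_count_is_arithmetic():
    cluster = WindowCluster("P1", tuple(mv(i + 1, "A", "G") for i in range(30)))
    assert count_combinations(cluster) == 2**30 - 1 >= 1_000_000_000


class TestApplyVariants:
    def test_empty_subset_identity(self):
        assert apply_variants("MGCK", ()) == "MGCK"

    def test_hand_substitution(self):
        assert apply_variants("MGCK", (mv(2, "G", "C"),)) == "MCCK"

    def test_mismatch_guard_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            apply_variants("MACK", (mv(2, "G", "C"),))


class TestSingleEach:
    REF = "M" + "A" * 59

    def variants(self, n):
        return [mv(i + 2, "A", "G") for i in range(n)]

    def test_emits_one_sequence_per_variant(self):
        out = single_each_fallback(self.REF, self.variants(26))
        assert len(out) == 26
        for seq, subset in out:
            assert len(subset) == 1
            diffs = [i for i, (a, b) in enumerate(zip(self.REF, seq)) if a != b]
            assert len(diffs) == 1

    def test_threshold_boundary_uses_combinatorial_path(self):
        # variants >30 residues apart: 25 stays on the combinatorial path
        # (singleton clusters), 26 switches to Single-Each
        ref = "M" + "AAAAAAAAAK" * 135
        positions = [50 * i + 2 for i in range(26)]
        assert all(ref[p - 1] == "A" for p in positions)
        v25 = [mv(p, "A", "C", acc="P1") for p in positions[:25]]
        entries = forge_protein("P1", ref, v25, ForgeConfig())
        assert entries and all(len(e.applied_variants) == 1 for e in entries)
        v26 = [mv(p, "A", "C", acc="P1") for p in positions]
        entries26 = forge_protein("P1", ref, v26, ForgeConfig())
        assert len({e.variant_string for e in entries26}) == 26


class TestVariantPeptideExtraction:
    # cathepsin-B-style worked example: K->E at the K of 'CSK' lengthens
    # the covering tryptic peptide to 'CSEICEPGYSPTYKQDK'
    REF = "MAAAK" + "CSK" + "ICEPGYSPTYK" + "QDK" + "AAAGSPR"
    K_POS = 8  # the K of CSK

    def test_loss_of_lysine_lengthens_peptide(self):
        config = ForgeConfig()
        variant = mv(self.K_POS, "K", "E")
        entries = forge_protein("P1", self.REF, [variant], config)
        assert "CSEICEPGYSPTYKQDK" in {e.peptide_sequence for e in entries}

    def test_reference_digest_contains_csk(self):
        assert "CSK" in {p.sequence for p in digest(self.REF, max_missed=2)}

    def test_short_fully_tryptic_variant_peptide_filtered(self):
        # variant inside a 3-mer peptide whose missed-cleavage extensions
        # all stay under the minimum length
        ref = "MK" + "CAK" + "AK" + "GK" + "R"
        entries = forge_protein("P1", ref, [mv(3, "C", "Y")], ForgeConfig())
        assert all(len(e.peptide_sequence) >= 7 for e in entries)


def forged_entries(toy):
    config = ForgeConfig()
    accession = sorted(toy.proteome)[0]
    ref = toy.proteome[accession]
    # plant three variants, one a gain-of-cysteine
    positions = [i + 1 for i, aa in enumerate(ref) if aa not in "KRCWE"][:3]
    variants = [
        mv(positions[0], ref[positions[0] - 1], "C", acc=accession),
        mv(positions[1], ref[positions[1] - 1], "W", acc=accession),
        mv(positions[2], ref[positions[2] - 1], "E", acc=accession),
    ]
    return forge_protein(accession, ref, variants, config), ref, config


def test_forged_peptides_pass_filters_and_differ_from_reference(toy):
    entries, ref, config = forged_entries(toy)
    assert entries
    ref_peps = reference_peptide_set(ref, config)
    for e in entries:
        assert config.min_len <= len(e.peptide_sequence) <= config.max_len
        assert config.min_mass <= monoisotopic_mass(e.peptide_sequence) <= config.max_mass
        assert e.peptide_sequence not in ref_peps
        assert e.applied_variants  # carries at least one variant


def test_dedup_and_write_idempotent(toy, tmp_path):
    entries, _, _ = forged_entries(toy)
    p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
    dedup_and_write(entries, p1, sidecar_path=tmp_path / "a.tsv")
    dedup_and_write(list(reversed(entries)), p2, sidecar_path=tmp_path / "b.tsv")
    assert p1.read_bytes() == p2.read_bytes()
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_dedup_keeps_all_provenances(tmp_path):
    from cysvarforge.dbforge import VariantPeptideEntry

    v1, v2 = mv(3, "A", "C", acc="P1"), mv(3, "A", "C", acc="P2")
    e1 = VariantPeptideEntry("ACDEFGHIK", "P1", (v1,), start_index=2)
    e2 = VariantPeptideEntry("ACDEFGHIK", "P2", (v2,), start_index=5)
    unique, sidecar = dedup_and_write([e1, e2], tmp_path / "db.fasta",
                                      sidecar_path=tmp_path / "db.tsv")
    assert len(unique) == 1  # one FASTA record
    assert set(sidecar["protein_accession"]) == {"P1", "P2"}  # both parents


def test_search_mode_headers_are_accession_only(toy, tmp_path):
    entries, _, _ = forged_entries(toy)
    path = tmp_path / "db.fasta"
    dedup_and_write(entries, path, mode="search")
    headers = [l[1:].strip() for l in path.read_text().splitlines()
               if l.startswith(">")]
    assert headers and all("|" not in h for h in headers)


def test_empty_entry_list_writes_valid_empty_fasta(tmp_path):
    path = tmp_path / "empty.fasta"
    unique, sidecar = dedup_and_write([], path)
    assert unique == [] and path.read_text() == ""


class TestDecoys:
    def test_reversal_with_prefix(self):
        [(header, seq)] = generate_decoys([("P1", "PEPTIDEK")])
        assert header == "rev_P1" and seq == "KEDITPEP"

    def test_involution(self):
        original = [("P1", "PEPTIDEK")]
        assert generate_decoys(generate_decoys(original)) == original

    def test_target_decoy_counts(self, toy, tmp_path):
        entries, _, _ = forged_entries(toy)
        path = tmp_path / "db.fasta"
        unique, _ = dedup_and_write(entries, path, with_decoys=True)
        n_records = path.read_text().count(">")
        assert n_records == 2 * len(unique)


def test_shared_rna_wes_variant_merges_to_one_entry():
    ref = "MAAAK" + "CSK" + "ICEPGYSPTYK" + "QDK" + "AAAGSPR"
    both = MissenseVariant("P1", 8, "K", "E", sources=frozenset({"RNA", "WES"}))
    entries = forge_protein("P1", ref, [both])
    seqs = [e.peptide_sequence for e in entries]
    assert len(seqs) == len(set(seqs))
    assert all(e.sources == "RNA;WES" for e in entries)


@given(st.integers(1, 10))
@settings(max_examples=10, deadline=None)
def test_combination_law_property(n):
    cluster = WindowCluster("P1", tuple(mv(3 * i + 1, "A", "G") for i in range(n)))
    assert sum(1 for _ in enumerate_combinations(cluster)) == 2**n - 1
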