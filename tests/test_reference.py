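"""Reference loading, canonical tag extraction, and strand-aware matching."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from sagelnc.reference import (
    FORWARD,
    REVERSE,
    LncRNARecord,
    TagAssignment,
    assign_tags,
    extract_canonical_tag,
    load_reference,
    match_tag,
    merge_assignments,
)


def _record(gene_id, seqs, **kw):
    defaults = dict(gene_name="", chromosome="1", start=1, end=1000,
                    strand=1, biotype="lincRNA")
    defaults.update(kw)
    return LncRNARecord(ensembl_id=gene_id, transcript_sequences=seqs, **defaults)


def _random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def brute_force_match(tag, records):
    """Independent oracle: plain substring scan of CATG+tag on both strands."""
    query = "CATG" + tag
    hits = set()
    for rec in records:
        for seq in rec.transcript_sequences:
            if query in seq:
                hits.add((rec.ensembl_id, FORWARD))
            if reverse_complement(query) in seq:
                hits.add((rec.ensembl_id, REVERSE))
    return sorted(hits)


class TestLoadReference:
    def _write_inputs(self, tmp_path, rows, fasta_entries):
        gt = tmp_path / "genes.tsv"
        header = "ensembl_id\tgene_name\tchromosome\tstart\tend\tstrand\tbiotype\n"
        gt.write_text(header + "".join(
            f"{r[0]}\t{r[1]}\t1\t100\t200\t1\tlincRNA\n" for r in rows
        ))
        fa = tmp_path / "tx.fa"
        fa.write_text("".join(f">{i}\n{s}\n" for i, s in fasta_entries))
        return gt, fa

    def test_matching_ids_give_matchable_records(self, tmp_path):
        gt, fa = self._write_inputs(
            tmp_path, [("G1", "A"), ("G2", "B")],
            [("G1", "CATG" + "A" * 20), ("G2", "CATG" + "C" * 20)],
        )
        records = load_reference(gt, fa)
        assert len(records) == 2 and all(r.matchable for r in records)

    def test_record_without_sequence_is_flagged(self, tmp_path, caplog):
        gt, fa = self._write_inputs(
            tmp_path, [("G1", "A"), ("G2", "B")], [("G1", "ACGT" * 10)]
        )
        with caplog.at_level("WARNING"):
            records = load_reference(gt, fa)
        by_id = {r.ensembl_id: r for r in records}
        assert by_id["G1"].matchable and not by_id["G2"].matchable
        assert any("no transcript sequence" in r.message for r in caplog.records)

    def test_total_id_mismatch_is_an_error(self, tmp_path):
        gt, fa = self._write_inputs(
            tmp_path, [("G1", "A")], [("OTHER", "ACGT" * 10)]
        )
        with pytest.raises(ValueError, match="pairing"):
            load_reference(gt, fa)

    def test_id_remap_drops_unmapped_genes(self, tmp_path):
        gt, fa = self._write_inputs(
            tmp_path, [("G1", "A"), ("G2", "B"), ("G3", "C")],
            [(g, "ACGT" * 10) for g in ("G1", "G2", "G3")],
        )
        remap = tmp_path / "remap.tsv"
        remap.write_text("G1\tNEW1\nG3\tNEW3\n")
        records = load_reference(gt, fa, id_remap=remap)
        assert sorted(r.ensembl_id for r in records) == ["NEW1", "NEW3"]

    def test_transcript_to_gene_resolution(self, tmp_path):
        gt, fa = self._write_inputs(
            tmp_path, [("G1", "A")], [("T1", "CATG" + "G" * 20)]
        )
        tmap = tmp_path / "tmap.tsv"
        tmap.write_text("T1\tG1\n")
        records = load_reference(gt, fa, transcript_map=tmap)
        assert records[0].matchable


class TestExtractCanonicalTag:
    def test_single_site(self):
        assert extract_canonical_tag("TTTCATGAAAAAAAAAAGGG") == "AAAAAAAAAA"

    def test_three_prime_most_eligible_site_wins(self):
        assert extract_canonical_tag(
            "CATGAAAAAAAAAACCCCATGGGGGGGGGGGTT"
        ) == "GGGGGGGGGG"

    def test_no_site_returns_none(self):
        assert extract_canonical_tag("TTTTTT") is None

    def test_site_too_close_to_end_is_ineligible(self):
        # only site has 9 downstream bases; the earlier one wins instead
        assert extract_canonical_tag("CATGAAAAAAAAAA" + "CATG" + "G" * 9) \
            == "AAAAAAAAAA"

    def test_tag_with_n_is_rejected(self):
        assert extract_canonical_tag("CATG" + "AAAAANAAAA") is None

    def test_matches_exhaustive_site_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            seq = _random_seq(rng, int(rng.integers(20, 400)))
            sites = [
                seq[i + 4: i + 14]
                for i in range(len(seq) - 13)
                if seq[i: i + 4] == "CATG"
            ]
            expected = sites[-1] if sites else None
            assert extract_canonical_tag(seq) == expected


class TestMatchTag:
    def test_forward_example(self):
        rec = _record("G1", ["TTTCATGAAAAAAAAAAGGG"])
        assert match_tag("AAAAAAAAAA", [rec]) == [("G1", FORWARD)]

    def test_reverse_example(self):
        # embed revcomp(CATG + tag) = revcomp(tag) + CATG
        tag = "AAAAAAAAAA"
        rec = _record("G1", ["GG" + reverse_complement("CATG" + tag) + "CC"])
        assert match_tag(tag, [rec]) == [("G1", REVERSE)]

    def test_no_anchor_no_match(self):
        rec = _record("G1", ["AAAAAAAAAAAAAAAAAAAA"])  # tag present, CATG absent
        assert match_tag("AAAAAAAAAA", [rec]) == []

    def test_bare_tag_matching_when_anchor_not_required(self):
        rec = _record("G1", ["TTAAAAAAAAAATT"])
        assert match_tag("AAAAAAAAAA", [rec], require_catg_prefix=False) \
            == [("G1", FORWARD)]

    def test_agrees_with_brute_force_oracle_on_random_fixture(self):
        rng = np.random.default_rng(17)
        records = [
            _record(f"G{i}", [_random_seq(rng, int(rng.integers(100, 600)))])
            for i in range(100)
        ]
        # probe tags: random plus every canonical tag of the fixture
        tags = {_random_seq(rng, 10) for _ in range(100)}
        for rec in records:
            t = extract_canonical_tag(rec.transcript_sequences[0])
            if t:
                tags.add(t)
        for tag in sorted(tags):
            assert match_tag(tag, records) == brute_force_match(tag, records)

    def test_extracted_canonical_tag_always_forward_matches(self):
        rng = np.random.default_rng(23)
        for i in range(50):
            rec = _record(f"G{i}", [_random_seq(rng, 300)])
            tag = extract_canonical_tag(rec.transcript_sequences[0])
            if tag is None:
                continue
            assert (rec.ensembl_id, FORWARD) in match_tag(tag, [rec])


class TestAssignTags:
    def test_unique_forward_match_retained(self):
        rec = _record("G1", ["TTTCATGAAAAAAAAAAGGG"])
        result = assign_tags(["AAAAAAAAAA"], [rec])
        [a] = result.assignments
        assert (a.ensembl_id, a.orientation, a.n_targets) == ("G1", FORWARD, 1)

    def test_multi_target_tag_discarded_and_reported(self):
        seq = "TTTCATGAAAAAAAAAAGGG"
        recs = [_record("G1", [seq]), _record("G2", [seq])]
        result = assign_tags(["AAAAAAAAAA"], recs)
        assert result.assignments == []
        assert result.multi_mapped == {"AAAAAAAAAA": ["G1", "G2"]}

    def test_reverse_only_tag_excluded_but_tallied(self):
        tag = "AAAAAAAAAA"
        rec = _record("G1", [reverse_complement("CATG" + tag)])
        result = assign_tags([tag], [rec])
        assert result.assignments == []
        assert result.reverse_only == [tag]

    def test_forward_takes_precedence_over_reverse(self):
        tag = "AAAAAAAAAA"
        seq = "CATG" + tag + "TT" + reverse_complement("CATG" + tag)
        result = assign_tags([tag], [_record("G1", [seq])])
        assert len(result.assignments) == 1
        assert result.reverse_only == []

    def test_tallies_partition_the_input(self, default_study):
        rng = np.random.default_rng(2)
        truth = default_study.truth
        tags = sorted(
            set(truth.canonical_tags.values())
            | set(truth.decoy_tags[:50])
            | {_random_seq(rng, 10) for _ in range(50)}
        )
        result = assign_tags(tags, default_study.records)
        assert sum(result.tallies().values()) == len(tags)
        retained = [a.tag for a in result.assignments]
        assert len(retained) == len(set(retained))

    def test_strand_symmetry_swaps_forward_and_reverse(self):
        rng = np.random.default_rng(31)
        records = [
            _record(f"G{i}", [_random_seq(rng, 400)]) for i in range(40)
        ]
        flipped = [
            _record(r.ensembl_id,
                    [reverse_complement(s) for s in r.transcript_sequences])
            for r in records
        ]
        tags = [_random_seq(rng, 10) for _ in range(100)]
        for rec in records:
            t = extract_canonical_tag(rec.transcript_sequences[0])
            if t:
                tags.append(t)
        fwd = assign_tags(tags, records).tallies()
        rev = assign_tags(tags, flipped).tallies()
        assert fwd["reverse_only"] == len(
            [t for t in set(tags)
             if brute_force_match(t, records)
             and all(o == REVERSE for _, o in brute_force_match(t, records))]
        )
        # forward-matching tags become reverse-matching and vice versa
        assert fwd["unmatched"] == rev["unmatched"]
        assert (fwd["forward_retained"] + fwd["forward_multi_mapped"]
                + fwd["reverse_only"]
                == rev["forward_retained"] + rev["forward_multi_mapped"]
                + rev["reverse_only"])


class TestMergeAssignments:
    def test_agreeing_sources_keep_sequence_match(self):
        seq = TagAssignment("A" * 10, "G1", source="sequence_match")
        uni = TagAssignment("A" * 10, "G1", source="unigene")
        merged, conflicts = merge_assignments([seq], [uni])
        assert conflicts == {}
        assert merged[0].source == "sequence_match"

    def test_conflicting_sources_discard_the_tag(self):
        seq = TagAssignment("A" * 10, "G1", source="sequence_match")
        uni = TagAssignment("A" * 10, "G2", source="unigene")
        merged, conflicts = merge_assignments([seq], [uni])
        assert merged == []
        assert conflicts == {"A" * 10: ["G1", "G2"]}

    def test_union_of_disjoint_sources(self):
        seq = TagAssignment("A" * 10, "G1", source="sequence_match")
        uni = TagAssignment("C" * 10, "G2", source="unigene")
        merged, _ = merge_assignments([seq], [uni])
        assert sorted(a.tag for a in merged) == ["A" * 10, "C" * 10]
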