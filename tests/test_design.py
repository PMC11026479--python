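import numpy as np
import pandas as pd
import pytest

from utrscreen import design
from utrscreen.design import (
    BAMHI, DESIGN1, DESIGN2, ECORI, MOTIF_LAYOUT, MotifSpec, OligoLayout,
    assemble_oligo, design_saturation_panel, extract_utr_variants,
    filter_rare_variants, oligos_to_frame, read_bed, screen_sequences,
)
from utrscreen.seq import revcomp


class TestLayouts:
    def test_segment_sums_are_200(self):
        for layout in (DESIGN1, DESIGN2, MOTIF_LAYOUT):
            assert layout.segment_sum == 200

    def test_insert_lengths(self):
        assert DESIGN1.insert_len == 158
        assert DESIGN2.insert_len == 164
        assert MOTIF_LAYOUT.insert_len == 158

    def test_variant_is_centered(self):
        assert DESIGN2.variant_offset == 81
        assert DESIGN1.variant_offset == 78

    def test_assemble_produces_200nt(self):
        ins = "A" * 164
        full = DESIGN2.assemble(ins)
        assert len(full) == 200
        assert full[DESIGN2.insert_start: DESIGN2.insert_start + 164] == ins
        assert ECORI in full

    def test_design1_carries_both_sites(self):
        full = DESIGN1.assemble("A" * 158)
        assert ECORI in full and BAMHI in full

    def test_assemble_rejects_wrong_insert_length(self):
        with pytest.raises(ValueError, match="insert length"):
            DESIGN2.assemble("A" * 100)

    def test_inconsistent_layout_rejected(self):
        with pytest.raises(ValueError, match="segments sum"):
            OligoLayout(name="bad", insert_len=100)


class TestReadBed:
    def test_parses_fields_and_skips_headers(self):
        lines = [
            "# comment",
            "track name=utr",
            "chr1\t10\t50\tGENEA\t0\t+",
            "chr2\t5\t9",
        ]
        df = read_bed(lines)
        assert list(df.chrom) == ["chr1", "chr2"]
        assert list(df.start) == [10, 5]
        assert df.loc[0, "name"] == "GENEA"
        assert df.loc[1, "strand"] == "+"  # default

    def test_error_names_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            read_bed(["chr1\t1\t2", "chr1\tx\t2"])
        with pytest.raises(ValueError, match="line 1"):
            read_bed(["chr1\t5\t2"])
        with pytest.raises(ValueError, match="fewer than 3"):
            read_bed(["chr1\t5"])


class TestExtractUtrVariants:
    def _variants(self, positions):
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(len(positions))],
                "chrom": "chr1",
                "pos": positions,
                "ref": "A",
                "alt": "C",
                "gene": "",
                "strand": "+",
            }
        )

    def test_half_open_boundaries(self):
        utr = pd.DataFrame(
            [{"chrom": "chr1", "start": 10, "end": 20, "name": "G", "strand": "-"}]
        )
        # 1-based pos p is kept iff start <= p-1 < end, i.e. p in [11, 20]
        out = extract_utr_variants(self._variants([10, 11, 20, 21]), utr)
        assert list(out.variant_id) == ["v1", "v2"]
        assert set(out.gene) == {"G"}
        assert set(out.strand) == {"-"}

    def test_matches_bruteforce_on_random_input(self):
        rng = np.random.default_rng(3)
        ivs = []
        for i in range(30):
            s = int(rng.integers(0, 500))
            ivs.append({"chrom": f"chr{rng.integers(1, 4)}", "start": s,
                        "end": s + int(rng.integers(1, 60)),
                        "name": f"G{i}", "strand": "+"})
        utr = pd.DataFrame(ivs)
        var = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(200)],
                "chrom": [f"chr{rng.integers(1, 5)}" for _ in range(200)],
                "pos": rng.integers(1, 600, size=200),
                "ref": "A", "alt": "C", "gene": "", "strand": "+",
            }
        )
        out = extract_utr_variants(var, utr)
        expected = set()
        for v in var.itertuples(index=False):
            for iv in utr.itertuples(index=False):
                if iv.chrom == v.chrom and iv.start <= v.pos - 1 < iv.end:
                    expected.add(v.variant_id)
                    break
        assert set(out.variant_id) == expected

    def test_overlap_count(self):
        utr = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 50, "name": "A", "strand": "+"},
                {"chrom": "chr1", "start": 10, "end": 30, "name": "B", "strand": "+"},
            ]
        )
        out = extract_utr_variants(self._variants([15]), utr)
        assert out.loc[0, "n_overlaps"] == 2
        assert out.loc[0, "gene"] == "A"  # first interval annotates


class TestFilterRareVariants:
    def _frame(self):
        return pd.DataFrame(
            {
                "variant_id": ["a", "b", "c", "d", "e"],
                "ref": ["A", "A", "AT", "A", "A"],
                "alt": ["C", "C", "A", "C", "C"],
                "adjAF": [0.001, 0.01, 0.005, np.nan, 0.02],
                "cosmic_cnt": [0, 5, 3, 2, 1],
            }
        )

    def test_population_mode_strict_threshold(self):
        out = filter_rare_variants(self._frame(), max_af=0.01)
        # b is exactly at the threshold (not strictly below), c is an indel,
        # d has missing AF, e is common
        assert list(out.variant_id) == ["a"]
        assert out.attrs["n_missing_af"] == 1

    def test_somatic_mode_recurrence(self):
        out = filter_rare_variants(self._frame(), somatic=True)
        assert list(out.variant_id) == ["b", "d"]


class TestScreenSequences:
    def test_rejects_restriction_sites_both_strands(self):
        seqs = {
            "ok": "ATATATATAT",
            "fwd_ecori": "AT" + ECORI + "AT",
            "rc_bamhi": "AT" + revcomp(BAMHI) + "AT",
        }
        passed, fails = screen_sequences(seqs)
        assert passed == ["ok"]
        reasons = dict(zip(fails.id, fails.reason))
        assert reasons["fwd_ecori"] == "EcoRI"
        assert reasons["rc_bamhi"] == "BamHI"

    def test_empty_forbidden_set_errors(self):
        with pytest.raises(ValueError, match="must not be empty"):
            screen_sequences({"a": "ACGT"}, forbidden=[])


class TestAssembleOligo:
    def _genome(self, rng, n=500):
        return {"chr1": "".join(rng.choice(list("ACGT"), size=n))}

    def test_plus_strand_alleles_and_offset(self):
        rng = np.random.default_rng(1)
        genome = self._genome(rng)
        pos = 250
        ref = genome["chr1"][pos - 1]
        alt = next(b for b in "ACGT" if b != ref)
        var = {"variant_id": "v1", "chrom": "chr1", "pos": pos, "ref": ref,
               "alt": alt, "strand": "+"}
        oref, oalt = assemble_oligo(var, genome, DESIGN2)
        off = DESIGN2.variant_offset
        assert len(oref.full_sequence) == 200
        assert oref.insert_sequence[off] == ref
        assert oalt.insert_sequence[off] == alt
        diffs = [i for i, (a, b) in enumerate(
            zip(oref.insert_sequence, oalt.insert_sequence)) if a != b]
        assert diffs == [off]
        # insert equals the genomic window on the plus strand
        start = pos - 1 - off
        assert oref.insert_sequence == genome["chr1"][start:start + 164]

    def test_minus_strand_reverse_complements(self):
        rng = np.random.default_rng(2)
        genome = self._genome(rng)
        pos = 250
        ref = genome["chr1"][pos - 1]
        alt = next(b for b in "ACGT" if b != ref)
        var = {"variant_id": "v1", "chrom": "chr1", "pos": pos, "ref": ref,
               "alt": alt, "strand": "-"}
        oref, _ = assemble_oligo(var, genome, DESIGN2)
        off = DESIGN2.variant_offset
        # the insert is the reverse complement of a plus-strand window and
        # carries the complemented ref base at the centered offset
        up = DESIGN2.insert_len - 1 - off
        window = genome["chr1"][pos - 1 - up: pos - 1 - up + 164]
        assert oref.insert_sequence == revcomp(window)
        assert oref.insert_sequence[off] == revcomp(ref)

    def test_reference_mismatch_raises(self):
        genome = {"chr1": "A" * 400}
        var = {"variant_id": "v", "chrom": "chr1", "pos": 200, "ref": "C",
               "alt": "G", "strand": "+"}
        with pytest.raises(ValueError, match="mismatch"):
            assemble_oligo(var, genome, DESIGN2)

    def test_window_outside_sequence_raises(self):
        genome = {"chr1": "A" * 100}
        var = {"variant_id": "v", "chrom": "chr1", "pos": 5, "ref": "A",
               "alt": "G", "strand": "+"}
        with pytest.raises(ValueError, match="extend"):
            assemble_oligo(var, genome, DESIGN2)

    def test_frame_adds_full_offset(self):
        genome = {"chr1": "ACGT" * 200}
        pos = 400
        ref = genome["chr1"][pos - 1]
        alt = "A" if ref != "A" else "C"
        var = {"variant_id": "v", "chrom": "chr1", "pos": pos, "ref": ref,
               "alt": alt, "strand": "+"}
        df = oligos_to_frame(assemble_oligo(var, genome, DESIGN2), DESIGN2)
        expected = DESIGN2.insert_start + DESIGN2.variant_offset
        assert set(df.full_variant_offset) == {expected}
        for row in df.itertuples(index=False):
            assert row.full_sequence[row.full_variant_offset] == \
                row.insert_sequence[row.variant_offset]


class TestSaturationPanel:
    def test_panel_size_and_regions(self):
        rng = np.random.default_rng(4)
        context = "".join(rng.choice(list("ACGT"), size=158))
        motif = context[60:68]
        spec = MotifSpec(motif_id="m1", motif_sequence=motif,
                         flank_up=5, flank_down=4)
        panel = design_saturation_panel(spec, context, motif_start=60)
        assert len(panel) == 1 + 3 * (8 + 5 + 4)
        assert (panel.full_sequence.str.len() == 200).all()
        assert (panel[panel.position.between(60, 67)]["region"] == "motif").all()
        assert set(panel[panel.position >= 0].region) == {"motif", "flank"}
        # every mutant differs from the reference at exactly its position
        ref_seq = panel.loc[0, "insert_sequence"]
        for row in panel.iloc[1:].itertuples(index=False):
            diffs = [i for i, (a, b) in enumerate(
                zip(ref_seq, row.insert_sequence)) if a != b]
            assert diffs == [row.position]

    def test_motif_must_match_context(self):
        context = "A" * 158
        spec = MotifSpec(motif_id="m", motif_sequence="TTTT")
        with pytest.raises(ValueError, match="motif sequence not found"):
            design_saturation_panel(spec, context, motif_start=60)
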