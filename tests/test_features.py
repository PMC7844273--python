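"""Feature-table parsing, geometry and spacer arithmetic."""

import numpy as np
import pytest

from mitorearr import (
    FormatError,
    GeneFeature,
    MitogenomeAnnotation,
    ValidationError,
    classify_stop_codon,
    feature_length,
    intergenic_spacers,
    parse_feature_table,
    write_feature_table,
)
from mitorearr.data import (
    cross_check_intergenic,
    load_printed_intergenic,
)
from mitorearr.synth import REFERENCE_GENE_LENGTHS


class TestReferenceTable:
    def test_composition_of_feature_classes(self, eel_annotation):
        assert len(eel_annotation.features) == 40
        assert eel_annotation.class_counts() == {
            "PCG": 13, "tRNA": 22, "rRNA": 2, "CR": 2, "OL": 1,
        }
        assert eel_annotation.genome_length == 17673
        assert max(f.end for f in eel_annotation.features) == 17673

    def test_every_printed_length_recomputes_from_coordinates(self, eel_annotation):
        for f in eel_annotation.features:
            label = f.name[3:] if f.name.startswith("trn") else f.name
            assert f.length(17673) == REFERENCE_GENE_LENGTHS[label], f.name

    def test_coi_out_of_frame_is_warned_not_rejected(self, eel_annotation):
        assert any("COI" in w for w in eel_annotation.warnings)
        assert len(eel_annotation.warnings) == 1

    def test_spacer_totals_computed_and_published(self, eel_annotation):
        sp = intergenic_spacers(eel_annotation)
        assert sp.n_spacers == 12
        assert sp.total_spacer_nt == 93  # coordinate-derived
        printed = load_printed_intergenic()
        assert sum(g for g in printed.values() if g > 0) == 89  # published column
        assert sum(1 for g in printed.values() if g > 0) == 12
        assert sp.gap("ND5", "Cytb") == 35
        assert sp.gap("ATP8", "ATP6") == -10

    def test_published_column_disagrees_only_around_ol(self, eel_annotation):
        mismatches = cross_check_intergenic(eel_annotation)
        assert {(u, d) for u, d, _, _ in mismatches} == {
            ("trnN", "OL"), ("OL", "trnC"),
        }

    def test_roundtrip_through_tsv(self, eel_annotation, tmp_path):
        p = tmp_path / "ann.tsv"
        write_feature_table(eel_annotation, p)
        again = parse_feature_table(p)
        assert again.features == eel_annotation.features
        assert again.genome_length == eel_annotation.genome_length


class TestFeatureLength:
    @pytest.mark.parametrize(
        "start,end,genome,expected",
        [
            (12034, 13890, 17673, 1857),  # ND5
            (15142, 16043, 17673, 902),   # CR1
            (5, 5, 100, 1),
            (17670, 4, 17673, 8),         # wraps the origin: 17670..17673 + 1..4
            (1, 50, 50, 50),              # feature spanning the whole genome
        ],
    )
    def test_length(self, start, end, genome, expected):
        f = GeneFeature("x", "CR", start, end, "H")
        assert feature_length(f, genome) == expected


class TestValidation:
    def test_end_beyond_genome_rejected(self):
        f = GeneFeature("bad", "tRNA", 10, 200, "H")
        with pytest.raises(ValidationError, match="bad"):
            MitogenomeAnnotation(genome_length=100, features=(f,))

    def test_duplicate_names_rejected(self):
        fs = (
            GeneFeature("CR", "CR", 1, 10, "H"),
            GeneFeature("CR", "CR", 11, 20, "H"),
        )
        with pytest.raises(ValidationError, match="duplicate"):
            MitogenomeAnnotation(genome_length=20, features=fs)

    def test_single_full_span_feature_is_valid(self):
        a = MitogenomeAnnotation(
            genome_length=70,
            features=(GeneFeature("trnX", "tRNA", 1, 70, "H"),),
        )
        assert a.features[0].length(70) == 70
        assert not a.warnings

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "broken.tsv"
        p.write_text("# genome_length=100\nname\tclass\tstart\tend\n")
        with pytest.raises(FormatError, match="strand"):
            parse_feature_table(p)


class TestSpacers:
    def test_abutting_features_gap_zero(self):
        a = MitogenomeAnnotation(
            genome_length=20,
            features=(
                GeneFeature("a", "CR", 1, 10, "H"),
                GeneFeature("b", "CR", 11, 20, "H"),
            ),
        )
        sp = intergenic_spacers(a)
        assert sp.gap("a", "b") == 0
        assert sp.gap("b", "a") == 0  # wrap junction

    @pytest.mark.parametrize("seed", range(5))
    def test_tiled_circle_conserves_length(self, seed):
        # sum of feature lengths plus all gaps (wrap included) equals the
        # genome length for any circular layout without overlaps
        rng = np.random.default_rng(seed)
        pos = 1
        feats = []
        for i in range(rng.integers(3, 12)):
            gap = int(rng.integers(0, 30))
            length = int(rng.integers(1, 500))
            start = pos + gap
            feats.append(GeneFeature(f"g{i}", "CR", start, start + length - 1, "H"))
            pos = start + length
        wrap = int(rng.integers(0, 20))
        genome_length = pos - 1 + wrap
        a = MitogenomeAnnotation(genome_length=genome_length, features=tuple(feats))
        sp = intergenic_spacers(a)
        total_len = sum(f.length(genome_length) for f in feats)
        total_gap = sum(g for _, _, g in sp.pairs)
        assert total_len + total_gap == genome_length


class TestStopCodons:
    @pytest.mark.parametrize(
        "stop,kind",
        [
            ("TAA", "complete"), ("TAG", "complete"),
            ("AGA", "complete"), ("AGG", "complete"),
            ("T-", "incomplete"), ("TA-", "incomplete"),
        ],
    )
    def test_classification(self, stop, kind):
        assert classify_stop_codon(stop) == kind

    def test_unknown_token_rejected(self):
        with pytest.raises(ValidationError):
            classify_stop_codon("TGA")


class TestGenBank:
    def test_genbank_flat_file_maps_classes_and_disambiguates(self, tmp_path):
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqFeature import SeqFeature, SimpleLocation
        from Bio.SeqRecord import SeqRecord

        seq = Seq("ACGT" * 50)
        rec = SeqRecord(seq, id="TEST1", annotations={
            "molecule_type": "DNA", "topology": "circular", "organism": "test organism",
        })
        rec.features = [
            SeqFeature(SimpleLocation(0, 30, 1), type="CDS",
                       qualifiers={"gene": ["ND1"]}),
            SeqFeature(SimpleLocation(30, 100, -1), type="tRNA",
                       qualifiers={"gene": ["trnQ"]}),
            SeqFeature(SimpleLocation(100, 140, 1), type="D-loop",
                       qualifiers={"gene": ["CR"]}),
            SeqFeature(SimpleLocation(150, 190, 1), type="D-loop",
                       qualifiers={"gene": ["CR"]}),
        ]
        p = tmp_path / "mini.gb"
        SeqIO.write(rec, str(p), "genbank")

        ann = parse_feature_table(p, format="genbank")
        by_name = {f.name: f for f in ann.features}
        assert by_name["ND1"].gene_class == "PCG"
        assert by_name["ND1"].start == 1 and by_name["ND1"].end == 30
        assert by_name["trnQ"].strand == "L"
        assert {"CR1", "CR2"} <= set(by_name)
        assert ann.circular and ann.organism == "test organism"
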