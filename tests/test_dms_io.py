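"""Parsing and validation of score sets, PSSM files and prediction tables."""

import numpy as np
import pytest

from dmsbench.dms_io import (
    PssmProfile,
    check_sequence_consistency,
    read_pssm,
    read_prediction_table,
    read_scoreset,
    write_pssm,
    write_scoreset,
)
from dmsbench.errors import (
    ConfigurationError,
    FormatError,
    SequenceMismatchError,
    ValidationError,
)
from dmsbench.predictors import MethodSpec

from conftest import make_dataset

# First rows of a PSSM emitted by a real psiblast run (3 iterations) on a
# toy query, frozen verbatim to pin the dialect.
PSIBLAST_PSSM = """\
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M    -1  -2  -3  -1   0  -2  -3  -2   1   2  -1   6   0  -3  -2  -1  -1  -1   1  -1    0   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0  0.34 0.00
    2 K    -1   4   0  -1  -3   1   1  -2  -1  -3  -2   4  -1  -3  -1   0  -1  -3  -2  -2    0  35   0   0   0   0   0   0   0   0   0  65   0   0   0   0   0   0   0   0  0.52 0.00
    3 V     0  -3  -3  -3  -1  -2  -2  -3  -3   3   1  -2   1  -1  -2  -2   0  -3  -1   4    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0 100  0.34 0.00

                      K         Lambda
Standard Ungapped    0.1374     0.3224
Standard Gapped      0.0410     0.2670
"""


def write_table(tmp_path, rows, header, name="scores.tsv", sep="\t"):
    path = tmp_path / name
    lines = [sep.join(header)] + [sep.join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadScoreset:
    HEADER = ["protein_id", "position", "wt_aa", "mut_aa", "raw_score",
              "is_synonymous"]

    def test_parses_savs_and_synonymous(self, tmp_path):
        path = write_table(tmp_path, [
            ("P1", 1, "A", "V", 0.2, False),
            ("P1", 1, "A", "G", -1.3, False),
            ("P1", 1, "A", "A", 0.01, True),
            ("P1", 2, "L", "P", -2.0, False),
        ], self.HEADER)
        ds = read_scoreset(path, wt_score=0.0)
        assert len(ds.savs) == 3
        assert len(ds.synonymous) == 1
        assert ds.synonymous[0].raw_score == pytest.approx(0.01)

    def test_column_map_is_transparent(self, tmp_path):
        rows = [("P1", 3, "A", "V", 0.5, False)]
        plain = write_table(tmp_path, rows, self.HEADER, "a.tsv")
        mapped_header = ["protein_id", "aa_pos", "wt_aa", "mut_aa",
                         "raw_score", "is_synonymous"]
        mapped = write_table(tmp_path, rows, mapped_header, "b.tsv")
        ds_a = read_scoreset(plain, dataset_id="ds")
        ds_b = read_scoreset(mapped, column_map={"position": "aa_pos"},
                             dataset_id="ds")
        assert ds_a.variants == ds_b.variants

    def test_nonstandard_residue_rejected(self, tmp_path):
        path = write_table(tmp_path, [("P1", 1, "A", "X", 0.5, False)],
                           self.HEADER)
        with pytest.raises(ValidationError, match="mut_aa"):
            read_scoreset(path)

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = write_table(tmp_path, [("P1", 1, "A", "V")],
                           ["protein_id", "position", "wt_aa", "mut_aa"])
        with pytest.raises(ConfigurationError, match="raw_score"):
            read_scoreset(path)

    def test_conflicting_duplicates_rejected_identical_deduplicated(
            self, tmp_path):
        path = write_table(tmp_path, [
            ("P1", 1, "A", "V", 0.5, False),
            ("P1", 1, "A", "V", 0.5, False),
        ], self.HEADER, "dup.tsv")
        assert len(read_scoreset(path).savs) == 1
        path = write_table(tmp_path, [
            ("P1", 1, "A", "V", 0.5, False),
            ("P1", 1, "A", "V", 0.7, False),
        ], self.HEADER, "conflict.tsv")
        with pytest.raises(ValidationError, match="A1V"):
            read_scoreset(path)

    def test_unparseable_scores_dropped(self, tmp_path):
        path = write_table(tmp_path, [
            ("P1", 1, "A", "V", 0.5, False),
            ("P1", 1, "A", "G", "n.d.", False),
        ], self.HEADER)
        assert len(read_scoreset(path).savs) == 1

    def test_categorical_scores_rejected(self, tmp_path):
        path = write_table(tmp_path, [
            ("P1", 1, "A", "V", "strong", False),
            ("P1", 1, "A", "G", "weak", False),
        ], self.HEADER)
        with pytest.raises(ValidationError, match="categorical"):
            read_scoreset(path)

    def test_write_read_round_trip(self, tmp_path):
        ds = make_dataset([(1, "A", "V", 0.25), (1, "A", "A", 0.01),
                           (2, "L", "P", -2.0)])
        out = tmp_path / "rt.tsv"
        write_scoreset(ds, out)
        again = read_scoreset(out, dataset_id=ds.dataset_id)
        assert again.variants == ds.variants


class TestSequenceConsistency:
    def test_full_match_zero_flags(self):
        ds = make_dataset([(1, "M", "V", -1.0), (3, "V", "A", -0.5)])
        checked = check_sequence_consistency(ds, "MKV")
        assert checked.flagged_positions == []
        assert checked.sequence == "MKV"

    def test_two_mismatches_in_100_accepted_with_flags(self):
        seq = "A" * 100
        ds = make_dataset([(i, "A", "V", -1.0) for i in range(1, 99)]
                          + [(99, "C", "V", -1.0), (100, "C", "V", -1.0)])
        checked = check_sequence_consistency(ds, seq)
        assert checked.flagged_positions == [99, 100]

    def test_six_mismatches_rejected(self):
        seq = "A" * 100
        ds = make_dataset([(i, "C", "V", -1.0) for i in range(1, 7)])
        with pytest.raises(SequenceMismatchError) as exc:
            check_sequence_consistency(ds, seq)
        assert exc.value.positions == [1, 2, 3, 4, 5, 6]

    def test_idempotent(self):
        seq = "A" * 50
        ds = make_dataset([(1, "A", "V", -1.0), (2, "C", "V", -1.0)])
        once = check_sequence_consistency(ds, seq)
        twice = check_sequence_consistency(once, seq)
        assert once.flagged_positions == twice.flagged_positions


class TestReadPssm:
    def test_parses_real_psiblast_output(self, tmp_path):
        path = tmp_path / "toy.pssm"
        path.write_text(PSIBLAST_PSSM)
        profile = read_pssm(path)
        assert profile.sequence == "MKV"
        assert profile.log_odds[0].tolist() == [
            -1, -2, -3, -1, 0, -2, -3, -2, 1, 2, -1, 6, 0, -3, -2, -1, -1,
            -1, 1, -1]
        assert profile.score(2, "R") == 4

    def test_whitespace_insensitive(self, tmp_path):
        import re
        squeezed = re.sub(r"[ ]+", " ", PSIBLAST_PSSM)
        a, b = tmp_path / "a.pssm", tmp_path / "b.pssm"
        a.write_text(PSIBLAST_PSSM)
        b.write_text(squeezed)
        assert read_pssm(a, "p") == read_pssm(b, "p")

    def test_percentage_block_optional(self, tmp_path):
        lines = []
        for line in PSIBLAST_PSSM.splitlines():
            parts = line.split()
            if parts and parts[0].isdigit():
                lines.append(" ".join(parts[:22]))
            else:
                lines.append(line)
        path = tmp_path / "short.pssm"
        path.write_text("\n".join(lines) + "\n")
        profile = read_pssm(path, "p")
        full = read_pssm_text(tmp_path, PSIBLAST_PSSM)
        assert profile == PssmProfile("p", full.sequence, full.log_odds)

    def test_truncated_row_reports_line_number(self, tmp_path):
        bad = "\n".join([
            "header",
            "    1 M    -1  -2  -3  -1   0  -2  -3  -2   1   2  -1   6   0"
            "  -3  -2  -1  -1  -1   1  -1",
            "    2 K    -1   4   0",
        ])
        path = tmp_path / "bad.pssm"
        path.write_text(bad + "\n")
        with pytest.raises(FormatError, match=":3"):
            read_pssm(path)

    def test_empty_body_rejected(self, tmp_path):
        path = tmp_path / "empty.pssm"
        path.write_text("Last position-specific scoring matrix computed\n")
        with pytest.raises(FormatError, match="no PSSM rows"):
            read_pssm(path)

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        profile = PssmProfile("p", "MKVL",
                              rng.integers(-10, 10, size=(4, 20)))
        out = tmp_path / "out.pssm"
        write_pssm(profile, out)
        assert read_pssm(out, "p") == profile


def read_pssm_text(tmp_path, text):
    path = tmp_path / "_ref.pssm"
    path.write_text(text)
    return read_pssm(path, "p")


class TestReadPredictionTable:
    HEADER = ["protein_id", "position", "wt_aa", "mut_aa", "raw_score"]
    SNAP2 = MethodSpec("snap2", raw_min=-100, raw_max=100,
                       default_threshold=0)

    def test_in_range_scores_accepted(self, tmp_path):
        path = write_table(tmp_path, [("P1", 1, "A", "V", 83),
                                      ("P1", 1, "A", "G", -57)], self.HEADER)
        pred = read_prediction_table(path, self.SNAP2)
        assert pred.scores[("P1", 1, "A", "V")] == 83

    def test_out_of_range_score_rejected(self, tmp_path):
        unit = MethodSpec("m", raw_min=0, raw_max=1, default_threshold=0.5)
        path = write_table(tmp_path, [("P1", 1, "A", "V", 1.2)], self.HEADER)
        with pytest.raises(ValidationError, match="1.2"):
            read_prediction_table(path, unit)

    def test_empty_table_is_valid_and_empty(self, tmp_path):
        path = write_table(tmp_path, [], self.HEADER)
        pred = read_prediction_table(path, self.SNAP2)
        assert len(pred) == 0
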