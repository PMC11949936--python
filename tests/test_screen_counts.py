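import numpy as np
import pandas as pd
import pytest

from tilescreen import (
    CountMatrix,
    FormatError,
    GenomicInterval,
    GuideLibrary,
    Sample,
    SampleSheet,
    count_guides,
    extract_spacer,
    read_counts,
    read_sample_sheet,
    write_counts,
)
from tilescreen.library_design import reverse_complement
from tilescreen.screen_counts import write_sample_sheet
from conftest import make_guide

A5, A3 = "CCGGAACCGGTT", "GTTTAAACGGGT"


def fastq_record(i, seq):
    return f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n"


def write_fastq(path, seqs):
    path.write_text("".join(fastq_record(i, s) for i, s in enumerate(seqs)))


def embed(spacer, pad5="ACGT" * 3, pad3="TGCA" * 3):
    return pad5 + A5 + spacer + A3 + pad3


class TestExtractSpacer:
    def test_anchor_delimited_extraction(self):
        read = "CCGG" + "ACGTACGTACGTACGTACGT" + "GTTT"
        assert extract_spacer(read, "CCGG", "GTTT") == "ACGTACGTACGTACGTACGT"

    def test_missing_anchor5_yields_none(self):
        assert extract_spacer("AAAATTTTGGGG", "CCGG", "") is None

    def test_truncated_spacer_yields_none(self):
        assert extract_spacer("CCGG" + "ACGTACGT", "CCGG", "") is None

    def test_anchor3_mismatch_yields_none(self):
        read = "CCGG" + "A" * 20 + "TTTT"
        assert extract_spacer(read, "CCGG", "GGGG") is None

    def test_empty_anchor3_not_required(self):
        read = "CCGG" + "A" * 20 + "TTTT"
        assert extract_spacer(read, "CCGG", "") == "A" * 20

    def test_first_anchor5_occurrence_wins(self):
        read = "CCGG" + "T" * 20 + "CCGG" + "A" * 20
        assert extract_spacer(read, "CCGG", "") == "T" * 20


@pytest.fixture
def two_guide_library():
    return GuideLibrary(
        guides=[
            make_guide("g1", 100, spacer="ACGTACGTACGTACGTACGT"),
            make_guide("g2", 200, spacer="TTGCATGCATGCATGCATGC"),
        ],
        target_interval=GenomicInterval("chrS", 0, 1000),
    )


def sheet_for(tmp_path, files):
    samples = []
    for sid, (cond, rep, r1, r2) in files.items():
        samples.append(
            Sample(sample_id=sid, condition=cond, replicate=rep,
                   fastq_r1=str(r1), fastq_r2=None if r2 is None else str(r2))
        )
    return SampleSheet(samples=samples)


class TestCountGuides:
    def test_counts_match_generating_tally(self, tmp_path, two_guide_library):
        rng = np.random.default_rng(0)
        tallies = {}
        for sid, cond in [("s1", "sorted"), ("b1", "baseline")]:
            n1, n2 = rng.integers(50, 200, size=2)
            seqs = [embed("ACGTACGTACGTACGTACGT")] * n1 + [embed("TTGCATGCATGCATGCATGC")] * n2
            rng.shuffle(seqs)
            write_fastq(tmp_path / f"{sid}.fastq", seqs)
            tallies[sid] = (n1, n2)
        sheet = sheet_for(tmp_path, {
            "s1": ("sorted", 1, tmp_path / "s1.fastq", None),
            "b1": ("baseline", 1, tmp_path / "b1.fastq", None),
        })
        cm = count_guides(sheet, two_guide_library, A5, A3)
        for sid, (n1, n2) in tallies.items():
            assert cm.counts.loc["g1", sid] == n1
            assert cm.counts.loc["g2", sid] == n2
            assert cm.unassigned[sid] == 0

    def test_read_order_invariance(self, tmp_path, two_guide_library):
        seqs = [embed("ACGTACGTACGTACGTACGT")] * 5 + [embed("TTGCATGCATGCATGCATGC")] * 3
        write_fastq(tmp_path / "a.fastq", seqs)
        write_fastq(tmp_path / "b.fastq", seqs[::-1])
        sheet = sheet_for(tmp_path, {
            "a": ("sorted", 1, tmp_path / "a.fastq", None),
            "b": ("baseline", 1, tmp_path / "b.fastq", None),
        })
        cm = count_guides(sheet, two_guide_library, A5, A3)
        assert (cm.counts["a"] == cm.counts["b"]).all()

    def test_single_mismatch_rescue(self, tmp_path, two_guide_library):
        mutated = "GCGTACGTACGTACGTACGT"  # g1 spacer with one substitution
        write_fastq(tmp_path / "s.fastq", [embed(mutated)] * 4)
        write_fastq(tmp_path / "b.fastq", [embed("ACGTACGTACGTACGTACGT")])
        sheet = sheet_for(tmp_path, {
            "s": ("sorted", 1, tmp_path / "s.fastq", None),
            "b": ("baseline", 1, tmp_path / "b.fastq", None),
        })
        exact = count_guides(sheet, two_guide_library, A5, A3, max_mismatches=0)
        assert exact.counts.loc["g1", "s"] == 0
        assert exact.unassigned["s"] == 4
        rescued = count_guides(sheet, two_guide_library, A5, A3, max_mismatches=1)
        assert rescued.counts.loc["g1", "s"] == 4
        assert rescued.unassigned["s"] == 0

    def test_ambiguous_rescue_stays_unassigned(self, tmp_path):
        lib = GuideLibrary(
            guides=[
                make_guide("g1", 100, spacer="A" * 20),
                make_guide("g2", 200, spacer="A" * 19 + "C"),
            ],
            target_interval=GenomicInterval("chrS", 0, 1000),
        )
        # distance 1 from both g1 and g2
        write_fastq(tmp_path / "s.fastq", [embed("A" * 19 + "G")])
        write_fastq(tmp_path / "b.fastq", [embed("A" * 20)])
        sheet = sheet_for(tmp_path, {
            "s": ("sorted", 1, tmp_path / "s.fastq", None),
            "b": ("baseline", 1, tmp_path / "b.fastq", None),
        })
        cm = count_guides(sheet, lib, A5, A3, max_mismatches=1)
        assert cm.unassigned["s"] == 1
        assert cm.counts["s"].sum() == 0

    def test_empty_fastq_gives_zero_column(self, tmp_path, two_guide_library):
        (tmp_path / "s.fastq").write_text("")
        write_fastq(tmp_path / "b.fastq", [embed("A" * 20)])
        sheet = sheet_for(tmp_path, {
            "s": ("sorted", 1, tmp_path / "s.fastq", None),
            "b": ("baseline", 1, tmp_path / "b.fastq", None),
        })
        cm = count_guides(sheet, two_guide_library, A5, A3)
        assert cm.counts["s"].sum() == 0
        assert cm.unassigned["s"] == 0

    def test_conservation_assigned_plus_unassigned(self, tmp_path, two_guide_library):
        seqs = [embed("ACGTACGTACGTACGTACGT")] * 3 + ["T" * 60] * 2
        write_fastq(tmp_path / "s.fastq", seqs)
        write_fastq(tmp_path / "b.fastq", seqs)
        sheet = sheet_for(tmp_path, {
            "s": ("sorted", 1, tmp_path / "s.fastq", None),
            "b": ("baseline", 1, tmp_path / "b.fastq", None),
        })
        cm = count_guides(sheet, two_guide_library, A5, A3)
        assert (cm.total_reads() == 5).all()

    def test_r2_fallback_when_r1_empty_of_spacer(self, tmp_path, two_guide_library):
        write_fastq(tmp_path / "s1.fastq", ["T" * 60])
        write_fastq(tmp_path / "s2.fastq", [reverse_complement(embed("ACGTACGTACGTACGTACGT"))])
        write_fastq(tmp_path / "b.fastq", [embed("A" * 20)])
        sheet = sheet_for(tmp_path, {
            "s": ("sorted", 1, tmp_path / "s1.fastq", tmp_path / "s2.fastq"),
            "b": ("baseline", 1, tmp_path / "b.fastq", None),
        })
        cm = count_guides(sheet, two_guide_library, A5, A3)
        assert cm.counts.loc["g1", "s"] == 1

    def test_duplicate_library_spacers_rejected(self, tmp_path):
        lib = GuideLibrary(
            guides=[make_guide("g1", 100), make_guide("g2", 200)],
            target_interval=GenomicInterval("chrS", 0, 1000),
        )
        sheet = sheet_for(tmp_path, {
            "s": ("sorted", 1, tmp_path / "x.fastq", None),
            "b": ("baseline", 1, tmp_path / "x.fastq", None),
        })
        with pytest.raises(ValueError, match="unique"):
            count_guides(sheet, lib, A5, A3)


class TestCountsIO:
    def make_cm(self):
        counts = pd.DataFrame(
            {"s1": [3, 0], "b1": [1, 7]},
            index=pd.Index(["g1", "g2"], name="guide_id"),
        )
        return CountMatrix(counts=counts, unassigned=pd.Series({"s1": 2, "b1": 0}))

    def test_round_trip_identity(self, tmp_path):
        cm = self.make_cm()
        p = tmp_path / "counts.csv"
        write_counts(cm, p)
        back = read_counts(p)
        pd.testing.assert_frame_equal(back.counts, cm.counts)
        pd.testing.assert_series_equal(back.unassigned, cm.unassigned, check_names=False)

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "counts.csv"
        write_counts(self.make_cm(), p)
        p.write_text(p.read_text().replace("3,1", "-3,1"))
        with pytest.raises(FormatError, match="negative"):
            read_counts(p)

    def test_non_integer_value_rejected(self, tmp_path):
        p = tmp_path / "counts.csv"
        write_counts(self.make_cm(), p)
        p.write_text(p.read_text().replace("3,1", "3.5,1"))
        with pytest.raises(FormatError, match="integer"):
            read_counts(p)

    def test_sample_sheet_column_mismatch_rejected(self, tmp_path):
        p = tmp_path / "counts.csv"
        write_counts(self.make_cm(), p)
        sheet = SampleSheet(samples=[
            Sample("other", "sorted", 1), Sample("b1", "baseline", 1),
        ])
        with pytest.raises(FormatError, match="match"):
            read_counts(p, sheet=sheet)


class TestSampleSheet:
    def test_round_trip(self, tmp_path):
        sheet = SampleSheet(samples=[
            Sample("s1", "sorted", 1, fastq_r1="a.fastq"),
            Sample("b1", "baseline", 1, fastq_r1="b.fastq", fastq_r2="b2.fastq"),
        ])
        p = tmp_path / "sheet.csv"
        write_sample_sheet(sheet, p)
        back = read_sample_sheet(p)
        assert back.samples == sheet.samples

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SampleSheet(samples=[
                Sample("x", "sorted", 1), Sample("x", "baseline", 1),
            ])

    def test_both_conditions_required(self):
        with pytest.raises(ValueError, match="baseline"):
            SampleSheet(samples=[Sample("x", "sorted", 1)])

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            Sample("x", "treated", 1)
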