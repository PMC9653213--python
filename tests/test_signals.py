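"""Signal extractors versus brute-force oracles, orientation, and track I/O."""
import numpy as np
import pysam
import pytest

from clipmeta import (
    GenomeTrack,
    ReadFilterConfig,
    SignalTrack,
    coverage_from_alignments,
    export_track,
    mutations_from_alignments,
    signal_from_track,
    truncations_from_alignments,
)

from conftest import make_transcript, random_bam_with_md, write_bam
import oracles


def fetch_all(bam, chrom="chr1"):
    with pysam.AlignmentFile(str(bam)) as fh:
        return list(fh.fetch(chrom))


def test_single_read_full_coverage(tmp_path):
    t = make_transcript(exons=((100, 110),))
    bam = write_bam(tmp_path / "a.bam", [{"start": 100, "cigar": [(0, 10)]}])
    track = coverage_from_alignments(bam, t)
    assert track.values.tolist() == [1] * 10


def test_coverage_matches_pileup_oracle_known_cigars(tmp_path):
    """Deletions covered, N gaps not, soft clips consume no reference."""
    t = make_transcript(exons=((100, 150),))
    reads = [
        {"start": 100, "cigar": [(0, 20)]},
        {"start": 105, "cigar": [(0, 10), (2, 3), (0, 10)]},
        {"start": 110, "cigar": [(0, 5), (3, 20), (0, 5)]},
        {"start": 95, "cigar": [(4, 4), (0, 15)]},
        {"start": 140, "cigar": [(0, 8), (1, 2), (0, 10)]},
    ]
    bam = write_bam(tmp_path / "b.bam", reads)
    track = coverage_from_alignments(bam, t)
    expected = oracles.pileup_coverage(fetch_all(bam), 100, 50)
    np.testing.assert_array_equal(track.values, expected)
    # sum(coverage) equals summed aligned reference length within the span
    assert track.values.sum() == expected.sum()


def test_minus_strand_coverage_is_reversed(tmp_path):
    reads = [{"start": 100, "cigar": [(0, 12)]}, {"start": 120, "cigar": [(0, 30)]}]
    bam = write_bam(tmp_path / "c.bam", reads)
    plus = coverage_from_alignments(bam, make_transcript(exons=((100, 160),)))
    minus = coverage_from_alignments(bam, make_transcript(strand="-", exons=((100, 160),)))
    np.testing.assert_array_equal(minus.values, plus.values[::-1])


def test_truncation_offsets(tmp_path):
    t = make_transcript(exons=((100, 200),))
    # plus-strand read starting at 105: offset -1 -> transcript index 4
    bam = write_bam(tmp_path / "d.bam", [{"start": 105, "cigar": [(0, 20)]}])
    assert truncations_from_alignments(bam, t, offset=-1).values[4] == 1
    assert truncations_from_alignments(bam, t, offset=0).values[5] == 1
    # minus-strand read whose 5' end (rightmost base) is at genomic 140:
    # offset -1 walks one base further 3' in genome -> transcript index 41
    bam2 = write_bam(tmp_path / "e.bam", [{"start": 121, "cigar": [(0, 20)], "flag": 16}])
    track = truncations_from_alignments(bam2, t, offset=-1)
    assert track.values[41] == 1 and track.values.sum() == 1


def test_truncation_site_outside_span_dropped(tmp_path):
    t = make_transcript(exons=((100, 200),))
    bam = write_bam(tmp_path / "f.bam", [{"start": 100, "cigar": [(0, 20)]}])
    track = truncations_from_alignments(bam, t, offset=-1)  # site 99, outside
    assert track.values.sum() == 0


def test_each_read_contributes_at_most_one_truncation(tmp_path):
    t = make_transcript(exons=((100, 300),))
    reads = [{"start": 100 + 7 * i, "cigar": [(0, 25)]} for i in range(20)]
    bam = write_bam(tmp_path / "g.bam", reads)
    assert truncations_from_alignments(bam, t, offset=0).values.sum() <= len(reads)


def test_mutation_deletion_and_empty_kinds(tmp_path):
    t = make_transcript(exons=((100, 140),))
    bam = write_bam(tmp_path / "h.bam", [{"start": 105, "cigar": [(0, 10), (2, 2), (0, 10)]}])
    track = mutations_from_alignments(bam, t, kinds=("deletion",))
    assert track.values[15] == 1 and track.values[16] == 1 and track.values.sum() == 2
    assert mutations_from_alignments(bam, t, kinds=()).values.sum() == 0


def test_mutation_insertion_position(tmp_path):
    t = make_transcript(exons=((100, 140),))
    reads = [
        {"start": 105, "cigar": [(0, 10), (1, 2), (0, 10)]},
        {"start": 105, "cigar": [(0, 10), (1, 2), (0, 10)], "flag": 16, "name": "rev"},
    ]
    bam = write_bam(tmp_path / "i.bam", reads)
    track = mutations_from_alignments(bam, t, kinds=("insertion",))
    # forward read: base 5' of the insertion point is ref 114; reverse: 115
    assert track.values[14] == 1 and track.values[15] == 1


def test_mismatch_requires_md_or_reference(tmp_path):
    t = make_transcript(exons=((100, 140),))
    bam = write_bam(tmp_path / "j.bam", [{"start": 105, "cigar": [(0, 20)], "name": "nomd"}])
    with pytest.raises(ValueError, match="nomd"):
        mutations_from_alignments(bam, t, kinds=("mismatch",))
    # supplying a reference works without MD: read is all A over a C reference
    ref = {"chr1": "C" * 1000}
    track = mutations_from_alignments(bam, t, kinds=("mismatch",), reference=ref)
    assert track.values.sum() == 20


def test_mismatch_via_md_tag_matches_expansion_oracle(tmp_path, rng):
    bam, _ = random_bam_with_md(tmp_path / "k.bam", rng, n_reads=60, chrom_len=3000)
    t = make_transcript(exons=((0, 3000),))
    track = mutations_from_alignments(bam, t, kinds=("mismatch",))
    expected = oracles.mutation_counts(fetch_all(bam), 0, 3000, kinds=("mismatch",))
    np.testing.assert_array_equal(track.values, expected)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_randomized_extractors_match_oracles(tmp_path, rng, strand):
    bam, _ = random_bam_with_md(tmp_path / "l.bam", rng, n_reads=120, chrom_len=4000)
    t = make_transcript(strand=strand, exons=((500, 1500), (2000, 3500)))
    reads = [r for r in fetch_all(bam)]
    span_reads = [
        r for r in reads if r.reference_start < 3500 and r.reference_end > 500
    ]
    cov = coverage_from_alignments(bam, t)
    exp_cov = oracles.pileup_coverage(span_reads, 500, 3000)
    trunc = truncations_from_alignments(bam, t, offset=-1)
    exp_trunc = oracles.truncation_counts(reads, 500, 3000, offset=-1)
    mut = mutations_from_alignments(bam, t, kinds=("mismatch", "deletion", "insertion"))
    exp_mut = oracles.mutation_counts(span_reads, 500, 3000, kinds=("mismatch", "deletion", "insertion"))
    if strand == "-":
        exp_cov, exp_trunc, exp_mut = exp_cov[::-1], exp_trunc[::-1], exp_mut[::-1]
    np.testing.assert_array_equal(cov.values, exp_cov)
    np.testing.assert_array_equal(trunc.values, exp_trunc)
    np.testing.assert_array_equal(mut.values, exp_mut)


def test_read_filters(tmp_path):
    t = make_transcript(exons=((100, 200),))
    reads = [
        {"start": 100, "cigar": [(0, 20)], "name": "ok"},
        {"start": 100, "cigar": [(0, 20)], "name": "lowmapq", "mapq": 0},
        {"start": 100, "cigar": [(0, 20)], "name": "dup", "flag": 0x400},
        {"start": 100, "cigar": [(0, 20)], "name": "sec", "flag": 0x100},
        {"start": 100, "cigar": [(0, 20)], "name": "r1", "flag": 0x1 | 0x40},
        {"start": 100, "cigar": [(0, 20)], "name": "r2", "flag": 0x1 | 0x80},
    ]
    bam = write_bam(tmp_path / "m.bam", reads)
    # defaults: mapq>=1, no dups/secondary, paired -> read2 only
    assert coverage_from_alignments(bam, t).values.max() == 2  # ok + r2
    lax = ReadFilterConfig(min_mapq=0, exclude_duplicates=False, mate="both")
    assert coverage_from_alignments(bam, t, lax).values.max() == 5  # all but secondary
    r1only = ReadFilterConfig(mate="read1")
    assert coverage_from_alignments(bam, t, r1only).values.max() == 2  # ok + r1


def test_missing_index_raises(tmp_path):
    t = make_transcript(exons=((100, 200),))
    bam = write_bam(tmp_path / "n.bam", [{"start": 100, "cigar": [(0, 10)]}])
    (tmp_path / "n.bam.bai").unlink()
    with pytest.raises(ValueError, match="index"):
        coverage_from_alignments(bam, t)


def test_absent_chromosome_gives_zero_track(tmp_path, caplog):
    t = make_transcript(chrom="chrMissing", exons=((100, 200),))
    bam = write_bam(tmp_path / "o.bam", [{"start": 100, "cigar": [(0, 10)]}])
    track = coverage_from_alignments(bam, t)
    assert track.values.sum() == 0 and track.values.size == 100


def test_signal_from_track_basics():
    t = make_transcript(exons=((10, 20),))
    const = GenomeTrack({"chr1": np.full(100, 2.5)})
    np.testing.assert_array_equal(signal_from_track(t, plus=const).values, [2.5] * 10)
    single = np.zeros(100)
    single[12:15] = 7.0
    track = signal_from_track(t, plus=GenomeTrack({"chr1": single}))
    assert track.values.tolist() == [0, 0, 7, 7, 7, 0, 0, 0, 0, 0]


def test_signal_from_track_minus_strand_mirror():
    """Minus-strand extraction equals plus-strand extraction of the mirrored genome."""
    arr = np.arange(100, dtype=float)
    minus_t = make_transcript(strand="-", exons=((10, 20),))
    got = signal_from_track(minus_t, minus=GenomeTrack({"chr1": arr}))
    mirrored = arr[::-1].copy()  # reflect genome about its centre
    plus_t = make_transcript(exons=((100 - 20, 100 - 10),))
    exp = signal_from_track(plus_t, plus=GenomeTrack({"chr1": mirrored}))
    np.testing.assert_array_equal(got.values, exp.values)


def test_signal_from_track_beyond_chrom_raises():
    t = make_transcript(exons=((90, 120),))
    with pytest.raises(ValueError, match="beyond"):
        signal_from_track(t, plus=GenomeTrack({"chr1": np.zeros(100)}))


def test_export_track_round_trip_and_overlap(tmp_path):
    sizes = {"chr1": 1000}
    t1 = make_transcript("t1", exons=((100, 150),))
    t2 = make_transcript("t2", strand="-", exons=((300, 360),))
    rng = np.random.default_rng(7)
    s1 = SignalTrack("t1", "IP", "track_value", rng.integers(0, 5, 50).astype(float))
    s2 = SignalTrack("t2", "IP", "track_value", rng.integers(0, 5, 60).astype(float))
    paths = export_track([s1, s2], [t1, t2], sizes, tmp_path / "rt", fmt="bigwig")
    got1 = signal_from_track(t1, plus=paths["+"], minus=paths["-"])
    got2 = signal_from_track(t2, plus=paths["+"], minus=paths["-"])
    np.testing.assert_array_equal(got1.values, s1.values)
    np.testing.assert_array_equal(got2.values, s2.values)

    # overlapping transcripts on the same strand: values sum
    t3 = make_transcript("t3", exons=((120, 170),))
    s1u = SignalTrack("t1", "IP", "track_value", np.ones(50))
    s3u = SignalTrack("t3", "IP", "track_value", np.ones(50))
    paths = export_track([s1u, s3u], [t1, t3], sizes, tmp_path / "ov", fmt="bigwig")
    merged = signal_from_track(make_transcript(exons=((100, 170),)), plus=paths["+"])
    assert merged.values.max() == 2.0 and merged.values[25] == 2.0


def test_export_empty_collection_valid_files(tmp_path):
    import pyBigWig

    paths = export_track([], [], {"chr1": 500}, tmp_path / "empty")
    for p in paths.values():
        with pyBigWig.open(p) as bw:
            assert bw.chroms() == {"chr1": 500}


def test_export_track_wig_format(tmp_path):
    t1 = make_transcript("t1", exons=((10, 14),))
    s1 = SignalTrack("t1", "IP", "track_value", np.array([1.0, 2.0, 0.0, 3.0]))
    paths = export_track([s1], [t1], {"chr1": 30}, tmp_path / "w", fmt="wig")
    text = open(paths["+"]).read().splitlines()
    assert text[0] == "fixedStep chrom=chr1 start=1 step=1"
    assert [float(x) for x in text[1:]][10:14] == [1.0, 2.0, 0.0, 3.0]
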