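"""Read filtering cascade, exhaustive mapper and mismatch tallying."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnapjam import fidelity as fp
from rnapjam import synthetic_data as sd


def mk_read(seq, q=38, rid="r"):
    quals = tuple([q] * len(seq)) if isinstance(q, int) else tuple(q)
    return fp.Read(rid, seq, quals)


def to_reads(records):
    return [
        fp.Read(r.id, str(r.seq), tuple(r.letter_annotations["phred_quality"]))
        for r in records
    ]


# ---------------------------------------------------------------------------
# filters


def test_homopolymer_filter_rules():
    kept = fp.filter_homopolymer(
        [
            mk_read("ACGTTTTTACG", rid="five_ts"),  # run of 5 -> rejected
            mk_read("ACGAAAACGTA", rid="four_as"),  # run of 4 -> kept
            mk_read("ACGTACGTACG", rid="no_runs"),
        ]
    )
    assert [r.id for r in kept] == ["four_as", "no_runs"]


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.text(alphabet="ACGT", min_size=1, max_size=60))
def test_homopolymer_filter_matches_regex_oracle(seq):
    kept = fp.filter_homopolymer([mk_read(seq)])
    assert bool(kept) == (re.search(r"(.)\1{4}", seq) is None)


def test_trim_lengths_and_warnings():
    r135 = mk_read("A" * 60 + "C" * 2 + "ACGT" * 18 + "G", rid="x")
    assert len(r135) == 135
    (t,) = fp.trim_reads([r135])
    assert len(t) == 95
    assert len(t.qualities) == 95
    assert t.sequence == r135.sequence[20:115]
    with pytest.warns(UserWarning):
        (t41,) = fp.trim_reads([mk_read("ACGT" * 10 + "A", rid="r41")])
    assert len(t41) == 1
    assert fp.trim_reads([mk_read("ACGT" * 10, rid="r40")]) == []


def test_quality_filter_rules():
    keep = fp.quality_filter(
        [
            mk_read("ACGT" * 5, q=25, rid="all25"),
            mk_read("ACGT" * 5, q=[40] * 19 + [14], rid="one_low"),
            mk_read("ACGT" * 5, q=24, rid="mean_low"),
        ]
    )
    assert [r.id for r in keep] == ["all25"]


def test_read_validation():
    with pytest.raises(ValueError):
        fp.Read("bad", "ACGT", (30, 30, 30))
    with pytest.raises(ValueError):
        fp.Read("neg", "AC", (30, -1))


# ---------------------------------------------------------------------------
# mapper


@pytest.fixture(scope="module")
def reference():
    return sd.generate_reference(4000, gc=0.5, seed=101)


def test_mapper_places_exact_reads(reference):
    mapper = fp.Mapper(reference)
    sub = reference[1500:1595]
    a = mapper.map(mk_read(sub, rid="fwd"))
    assert (a.ref_start, a.strand, a.n_mismatches) == (1500, "+", 0)
    rc = str(sub)[::-1].translate(str.maketrans("ACGT", "TGCA"))
    b = mapper.map(mk_read(rc, rid="rev"))
    assert (b.ref_start, b.strand, b.n_mismatches) == (1500, "-", 0)


def test_mapper_mismatch_threshold_and_positions(reference):
    mapper = fp.Mapper(reference, max_mismatches=6)
    sub = list(reference[800:895])
    for i in (3, 50):  # two substitutions at known read positions
        sub[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sub[i]]
    a = mapper.map(mk_read("".join(sub), rid="two_mm"))
    assert a.n_mismatches == 2
    assert a.mismatch_read_positions == (4, 51)
    # seven more substitutions push the count over max_mismatches
    for i in (0, 10, 20, 30, 40, 60, 70):
        sub[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sub[i]]
    assert mapper.map(mk_read("".join(sub), rid="nine_mm")) is None


def test_mapper_discards_ambiguous_placements():
    core = sd.generate_reference(1000, gc=0.5, seed=3)
    dup = core + core[200:400] + core  # read from the duplicated block is ambiguous
    mapper = fp.Mapper(dup)
    assert mapper.map(mk_read(core[250:345], rid="amb")) is None
    with pytest.raises(ValueError):
        fp.Mapper("")


def test_mapper_excludes_n_bases(reference):
    mapper = fp.Mapper(reference)
    sub = reference[600:695]
    read = mk_read("N" + sub[1:], rid="with_n")
    a = mapper.map(read)
    assert a.n_mismatches == 0
    assert a.aligned_bases == 94  # N dropped from the denominator


# ---------------------------------------------------------------------------
# tally arithmetic


def test_tally_arithmetic():
    clean = [
        fp.Alignment(f"r{i}", 0, "+", 0, (), 95) for i in range(9)
    ]
    one_mm = [fp.Alignment("r9", 0, "+", 1, (12,), 95)]
    rep = fp.tally_mismatches(clean + one_mm)
    assert rep.total_aligned_bases == 950
    assert rep.total_mismatches == 1
    assert rep.per_read_mean == pytest.approx(0.1)
    assert rep.per_base_rate == pytest.approx(100.0 / 950)
    assert rep.reads_with_mismatch_fraction == pytest.approx(10.0)
    empty = fp.tally_mismatches([])
    assert np.isnan(empty.per_base_rate)


# ---------------------------------------------------------------------------
# full cascade


def test_pipeline_zero_errors(reference):
    records, _ = sd.generate_reads(reference, 300, model=sd.ErrorModel(seed=7))
    report, kept = fp.run_pipeline(to_reads(records), reference)
    assert report.per_base_rate == 0.0
    assert report.n_aligned_reads > 50
    counts = list(report.stage_counts.values())
    assert counts == sorted(counts, reverse=True)  # cascade only removes reads


def test_pipeline_stages_are_subsets(reference):
    records, _ = sd.generate_reads(
        reference, 400, model=sd.ErrorModel(e_seq=0.002, seed=8)
    )
    reads = to_reads(records)
    s1 = fp.filter_homopolymer(reads)
    s2 = fp.trim_reads(s1)
    s3 = fp.quality_filter(s2)
    ids = [set(r.id for r in stage) for stage in (reads, s1, s2, s3)]
    assert ids[0] >= ids[1] >= ids[2] >= ids[3]


def test_pipeline_recovers_injected_rate(reference):
    model = sd.ErrorModel(e_tx=0.001, e_rt=0.003, e_seq=0.001, seed=12)
    records, _ = sd.generate_reads(reference, 3000, model=model)
    report, _ = fp.run_pipeline(to_reads(records), reference)
    p = sd.combined_error_probability(model)
    n = report.total_aligned_bases
    assert n > 50_000
    band = 3 * np.sqrt(p * (1 - p) / n)
    assert abs(report.per_base_rate / 100 - p) < band


@pytest.mark.parametrize("channel", ["e_tx", "e_rt", "e_seq"])
def test_each_error_channel_raises_rate(reference, channel):
    """Paired seeds couple the draws: raising one channel adds errors."""
    base = dict(e_tx=0.0005, e_rt=0.0005, e_seq=0.0005, seed=33)
    lo = sd.ErrorModel(**base)
    hi = sd.ErrorModel(**{**base, channel: 0.004})
    reports = []
    for model in (lo, hi):
        records, _ = sd.generate_reads(reference, 1500, model=model)
        rep, _ = fp.run_pipeline(to_reads(records), reference)
        reports.append(rep)
    assert reports[1].per_base_rate > reports[0].per_base_rate


def test_per_base_rate_unbiased_across_seeds():
    """Mean pipeline estimate tracks the injected combined rate closely."""
    ref = sd.generate_reference(5000, gc=0.5, seed=77)
    rates, ns = [], []
    p = None
    for seed in range(30):
        model = sd.ErrorModel(e_tx=0.001, e_rt=0.003, e_seq=0.001, seed=1000 + seed)
        p = sd.combined_error_probability(model)
        records, _ = sd.generate_reads(ref, 2400, model=model)
        rep, _ = fp.run_pipeline(to_reads(records), ref)
        rates.append(rep.per_base_rate / 100)
        ns.append(rep.total_aligned_bases)
    rates = np.asarray(rates)
    bias = rates.mean() - p
    se = rates.std(ddof=1) / np.sqrt(len(rates))
    assert np.mean(ns) > 80_000
    assert abs(bias) < 2 * se


def test_report_tsv_round_trip(tmp_path, reference):
    records, _ = sd.generate_reads(reference, 100, model=sd.ErrorModel(seed=5))
    report, kept = fp.run_pipeline(to_reads(records), reference)
    out = tmp_path / "report.tsv"
    report.to_tsv(out)
    text = out.read_text()
    assert "per_base_rate" in text and "reads_after_mapped" in text
    fq = tmp_path / "kept.fastq"
    fp.write_fastq(kept, fq)
    back = fp.read_fastq(fq)
    assert [r.id for r in back] == [r.id for r in kept]
    assert back[0].qualities == kept[0].qualities
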