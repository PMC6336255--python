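"""Filter cascade, deduplication, ORF search and characterization."""

import numpy as np
import pytest

from lncflow.discovery import (
    CodingEvidence,
    characterize,
    deduplicate_transcripts,
    find_longest_orf,
    run_filter_cascade,
)
from lncflow.genome_io import GenomicInterval, TranscriptModel

from conftest import make_tx


def evidence(tid="t", cpc=-1.0, pfam=False, cov=5.0, ident=None, overlap=False):
    return CodingEvidence(tid, cpc, pfam, cov, ident, overlap)


def tx_of_length(tid, length):
    return make_tx(tid, "chr1", 1000, 1000 + length)


@pytest.mark.parametrize(
    "length,ev_kwargs,expected_step",
    [
        (150, {}, "length"),  # shorter than 200 bp is removed
        (300, {"cov": 2.0}, "coverage"),  # coverage below 3 removed
        (300, {"overlap": True}, "known_overlap"),
        (300, {"ident": 95.0}, "known_lnc_similarity"),  # >90% identity removed
        (300, {"cpc": -0.5, "ident": 50.0}, "none"),  # survives all steps
        (300, {"cpc": -0.5, "pfam": True}, "coding_potential"),
        (300, {"cpc": 0.5}, "coding_potential"),
    ],
)
def test_cascade_step_attribution(length, ev_kwargs, expected_step):
    tx = tx_of_length("t", length)
    (outcome,) = run_filter_cascade([tx], [evidence("t", **ev_kwargs)])
    assert outcome.failed_step == expected_step
    assert outcome.passed == (expected_step == "none")


@pytest.mark.parametrize(
    "length,ev_kwargs,passes",
    [
        (200, {}, True),  # exactly 200 bp kept ("shorter than 200" removed)
        (199, {}, False),
        (300, {"cov": 3.0}, True),  # coverage exactly 3 kept
        (300, {"ident": 90.0}, True),  # exactly 90% identity kept
        (300, {"ident": 90.0001}, False),
        (300, {"cpc": 0.0}, False),  # score 0 is not "< 0"
    ],
)
def test_cascade_boundary_semantics(length, ev_kwargs, passes):
    tx = tx_of_length("t", length)
    (outcome,) = run_filter_cascade([tx], [evidence("t", **ev_kwargs)])
    assert outcome.passed is passes


def test_cascade_first_violated_step_wins():
    """A transcript violating several steps is attributed to the earliest."""
    tx = tx_of_length("t", 100)  # fails length...
    ev = evidence("t", cpc=2.0, cov=0.5, overlap=True)  # ...and most others
    (outcome,) = run_filter_cascade([tx], [ev])
    assert outcome.failed_step == "length"


def test_cascade_order_invariance_and_intersection():
    """Survivors are the intersection of per-step pass sets, independent of
    input order."""
    rng = np.random.default_rng(5)
    txs, evs = [], []
    for i in range(50):
        tid = f"t{i}"
        txs.append(tx_of_length(tid, int(rng.integers(100, 600))))
        evs.append(
            evidence(
                tid,
                cpc=float(rng.uniform(-2, 2)),
                cov=float(rng.uniform(0, 10)),
                ident=float(rng.uniform(0, 100)),
                pfam=bool(rng.integers(2)),
            )
        )
    forward = {o.transcript_id: o for o in run_filter_cascade(txs, evs)}
    backward = {o.transcript_id: o for o in run_filter_cascade(txs[::-1], evs)}
    assert forward == backward
    ev_by_id = {e.transcript_id: e for e in evs}
    for tx in txs:
        e = ev_by_id[tx.transcript_id]
        in_intersection = (
            tx.length >= 200
            and e.read_coverage >= 3
            and not e.overlaps_known_coding
            and (e.known_lnc_identity is None or e.known_lnc_identity <= 90)
            and e.cpc_score < 0
            and not e.pfam_hit
        )
        assert forward[tx.transcript_id].passed == in_intersection


def test_cascade_monotone_in_thresholds():
    """Relaxing any single threshold never shrinks the survivor set."""
    rng = np.random.default_rng(9)
    txs, evs = [], []
    for i in range(80):
        tid = f"t{i}"
        txs.append(tx_of_length(tid, int(rng.integers(150, 400))))
        evs.append(
            evidence(
                tid,
                cpc=float(rng.uniform(-1, 1)),
                cov=float(rng.uniform(0, 6)),
                ident=float(rng.uniform(50, 100)),
            )
        )
    base = {o.transcript_id for o in run_filter_cascade(txs, evs) if o.passed}
    for relaxed in (
        dict(min_length=100),
        dict(min_coverage=1.0),
        dict(max_known_identity=99.0),
        dict(cpc_cutoff=0.5),
    ):
        survivors = {
            o.transcript_id for o in run_filter_cascade(txs, evs, **relaxed) if o.passed
        }
        assert base <= survivors


def test_missing_evidence_names_transcript():
    with pytest.raises(KeyError, match="t_missing"):
        run_filter_cascade([tx_of_length("t_missing", 300)], [])


def test_negative_coverage_rejected():
    with pytest.raises(ValueError):
        evidence(cov=-1.0)


def test_deduplicate_transcripts():
    a = make_tx("a", "chr1", 100, 300)
    b = make_tx("b", "chr1", 100, 300)  # identical structure, new id
    c = make_tx("c", "chr1", 100, 301)  # off by one bp
    d = make_tx("d", "chr1", 100, 300, strand="-")  # other strand
    out = deduplicate_transcripts([a, b, c, d])
    assert [t.transcript_id for t in out] == ["a", "c", "d"]
    assert deduplicate_transcripts([]) == []


def brute_force_orf(seq):
    best = 0
    stops = {"TAA", "TAG", "TGA"}
    for i in range(len(seq)):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in stops:
                best = max(best, j + 3 - i)
                break
    return best


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ATGAAATAG", 9),
        ("CCCCCC", 0),
        ("ATGAAA", 0),  # start without in-frame stop is not a complete ORF
        ("AATGAAATAGG", 9),  # frame 1
    ],
)
def test_find_longest_orf_examples(seq, expected):
    assert find_longest_orf(seq) == expected


def test_find_longest_orf_matches_exhaustive_scan():
    rng = np.random.default_rng(31)
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert find_longest_orf(seq) == brute_force_orf(seq)


def test_find_longest_orf_rejects_bad_alphabet():
    with pytest.raises(ValueError):
        find_longest_orf("ACGU")


def test_characterize():
    tx = TranscriptModel(
        "t1",
        "g1",
        (
            GenomicInterval("chr1", 100, 200),
            GenomicInterval("chr1", 300, 450),
        ),
    )
    single = make_tx("t2", "chr1", 100, 400)
    seqs = {"t1": "ATGAAATAGCCC", "t2": "CCC"}
    table = characterize([tx, single], seqs).set_index("transcript_id")
    assert table.loc["t1", "length"] == 250
    assert table.loc["t1", "n_exons"] == 2
    assert table.loc["t2", "n_exons"] == 1
    # ORF column equals the per-row search
    assert table.loc["t1", "orf_length"] == find_longest_orf(seqs["t1"])
    assert table.loc["t2", "orf_length"] == 0
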