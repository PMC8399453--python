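import math
from collections import Counter

import pytest

from patentscape.corpus import records_to_frame
from patentscape.preprocess import CleanConfig, clean_text, preprocess_corpus
from patentscape.synthetic import (
    GeneratorConfig,
    evaluate_recovery,
    generate_corpus,
    make_vocabulary,
)
from patentscape.vectorize import build_space, build_vectors, similarity_matrix


def small_cfg(**kw):
    base = dict(
        n_patents=40,
        n_topics=2,
        topic_vocab_size=20,
        background_vocab_size=30,
        tokens_per_field=40,
        seed=11,
    )
    base.update(kw)
    return GeneratorConfig(**base)


class FakePartition:
    def __init__(self, membership):
        self.membership = membership


def test_empty_corpus():
    records, truth = generate_corpus(small_cfg(n_patents=0))
    assert records == [] and truth.topics == {}


def test_same_seed_byte_identical():
    cfg = small_cfg()
    a, _ = generate_corpus(cfg)
    b, _ = generate_corpus(small_cfg())
    assert records_to_frame(a).to_csv() == records_to_frame(b).to_csv()
    c, _ = generate_corpus(small_cfg(seed=12))
    assert records_to_frame(a).to_csv() != records_to_frame(c).to_csv()


def test_vocabularies_survive_cleaning_and_are_distinct():
    words = make_vocabulary(200)
    assert len(set(words)) == 200
    cfg = CleanConfig()
    for w in words[:50]:
        assert clean_text(w, cfg).tokens == [w]


def test_mu_zero_gives_disjoint_inter_topic_vocabulary():
    cfg = small_cfg(mixing=0.0, form_term_rates={})
    records, truth = generate_corpus(cfg)
    streams = preprocess_corpus(records, "novelty")
    vectors = build_vectors(streams, 5)
    mat = similarity_matrix(vectors)
    pos = {pid: i for i, pid in enumerate(mat.ids)}
    for i, pi in enumerate(mat.ids):
        for pj in mat.ids[i + 1 :]:
            if truth.topics[pi] != truth.topics[pj]:
                # different topics share no words at all: c exactly 1
                assert mat.values[pos[pi], pos[pj]] == 1.0


def test_generator_bookkeeping_matches_cleaned_streams():
    records, truth = generate_corpus(small_cfg())
    for field in ("novelty", "use"):
        streams = preprocess_corpus(records, field)
        for pid, stream in streams.items():
            assert Counter(stream.tokens) == truth.emitted[pid][field]


def test_planted_forms_recorded_and_present_in_text():
    cfg = small_cfg(form_term_rates={"tablet": 1.0, "gel": 0.0})
    records, truth = generate_corpus(cfg)
    for r in records:
        assert truth.forms[r.patent_id] == {"tablet"}
        assert "tablet" in clean_text(r.use_text).tokens


def test_years_within_range():
    records, _ = generate_corpus(small_cfg(year_range=(2005, 2010)))
    assert all(2005 <= r.year <= 2010 for r in records)


def test_keyword_space_dimension_matches_bookkeeping():
    records, truth = generate_corpus(small_cfg())
    streams = preprocess_corpus(records, "novelty")
    vectors = build_vectors(streams, 5)
    space = build_space(vectors.values())
    realized = set()
    for vec in vectors.values():
        realized.update(w for w, _ in vec.words)
    assert space.dimension == len(realized)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        generate_corpus(small_cfg(mixing=1.5))
    with pytest.raises(ValueError):
        generate_corpus(small_cfg(form_term_rates={"tablet": -0.1}))
    with pytest.raises(ValueError):
        generate_corpus(small_cfg(n_topics=0))


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def test_recovery_perfect_up_to_relabeling():
    _, truth = generate_corpus(small_cfg())
    permuted = {pid: {0: "B", 1: "A"}[t] for pid, t in truth.topics.items()}
    scores = evaluate_recovery(FakePartition(permuted), truth)
    assert scores["nmi"] == pytest.approx(1.0)
    assert scores["ari"] == pytest.approx(1.0)


def test_recovery_zero_for_single_block():
    _, truth = generate_corpus(small_cfg())
    allsame = {pid: 1 for pid in truth.topics}
    scores = evaluate_recovery(FakePartition(allsame), truth)
    assert scores["nmi"] == pytest.approx(0.0, abs=1e-12)


def test_recovery_node_set_mismatch_rejected():
    _, truth = generate_corpus(small_cfg())
    part = {pid: 0 for pid in list(truth.topics)[:-1]}
    with pytest.raises(ValueError):
        evaluate_recovery(FakePartition(part), truth)


def test_recovery_matches_contingency_table_formulas():
    # 6 nodes: truth = [0,0,0,1,1,1], prediction = [0,0,1,1,2,2]
    truth = type("T", (), {})()
    truth.topics = {f"P{i}": t for i, t in enumerate([0, 0, 0, 1, 1, 1])}
    pred = {f"P{i}": c for i, c in enumerate([0, 0, 1, 1, 2, 2])}

    # direct evaluation from the 2x3 contingency table [[2,1,0],[0,1,2]]
    n = 6.0
    table = [[2, 1, 0], [0, 1, 2]]
    a = [sum(row) for row in table]
    b = [sum(col) for col in zip(*table)]
    mi = sum(
        nij / n * math.log(nij * n / (a[i] * b[j]))
        for i, row in enumerate(table)
        for j, nij in enumerate(row)
        if nij
    )
    h_true = -sum(x / n * math.log(x / n) for x in a)
    h_pred = -sum(x / n * math.log(x / n) for x in b)
    nmi_expected = mi / ((h_true + h_pred) / 2)

    comb2 = lambda x: x * (x - 1) / 2
    sum_ij = sum(comb2(nij) for row in table for nij in row)
    sum_a, sum_b = sum(map(comb2, a)), sum(map(comb2, b))
    expected_index = sum_a * sum_b / comb2(n)
    ari_expected = (sum_ij - expected_index) / ((sum_a + sum_b) / 2 - expected_index)

    scores = evaluate_recovery(FakePartition(pred), truth)
    assert scores["nmi"] == pytest.approx(nmi_expected, abs=1e-12)
    assert scores["ari"] == pytest.approx(ari_expected, abs=1e-12)


def test_recovery_degrades_as_mixing_increases():
    """Average pipeline recovery should fall monotonically over coarse
    mixing levels (averaged over seeds to damp noise)."""
    from patentscape.communities import louvain
    from patentscape.network import build_network, choose_threshold, lcc_sweep

    def run(mu, seed):
        cfg = GeneratorConfig(
            n_patents=60,
            n_topics=3,
            topic_vocab_size=25,
            background_vocab_size=40,
            tokens_per_field=50,
            mixing=mu,
            form_term_rates={},
            seed=seed,
        )
        records, truth = generate_corpus(cfg)
        streams = preprocess_corpus(records, "novelty")
        vectors = build_vectors(streams, 5)
        mat = similarity_matrix(vectors)
        h = choose_threshold(lcc_sweep(mat))
        g = build_network(mat, h)
        if g.number_of_edges() == 0:
            return 0.0
        part = louvain(g, seed=0)
        return evaluate_recovery(part, truth)["nmi"]

    means = []
    for mu in (0.0, 0.4, 0.8):
        means.append(sum(run(mu, s) for s in (1, 2, 3)) / 3)
    assert means[0] > means[-1]
    assert means[0] >= means[1] >= means[2] - 0.05
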