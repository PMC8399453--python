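"""End-to-end orchestration: corpus -> tokens -> vectors -> similarity
matrix -> threshold sweep -> network -> LCC -> degrees/exponent ->
communities -> keyword profiles -> dosage-form trends.

Every stage writes its tabular artifact into the run directory, and a
``metadata.json`` records the full configuration, seeds, scheme ids and
the headline counts (records in/excluded, vocabulary dimension d, LCC
size N, edges, communities, Q, gamma).  Reruns with the same
configuration produce byte-identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import communities as comm_mod
from . import network as net_mod
from . import trends as trends_mod
from . import vectorize as vec_mod
from .corpus import load_corpus, records_to_frame, write_table
from .preprocess import CleanConfig, preprocess_corpus
from .synthetic import GeneratorConfig, evaluate_recovery, generate_corpus

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: ``input_path`` (a patent table on disk) or
    ``generator`` (synthesize a corpus).  ``h`` left as None picks the
    threshold at the knee of the LCC sweep.
    """

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    field_name: str = "novelty"
    stopwords_path: str | None = None
    commonwords_path: str | None = None
    min_token_length: int = 2
    m: int = 5
    h: float | None = None
    h_grid: Sequence[float] = field(default_factory=lambda: list(net_mod.DEFAULT_H_GRID))
    include_zero_similarity: bool = True
    k_min: int = 1
    k_max: int = 100
    community_seed: int = 0
    lexicon_path: str | None = None
    out_dir: str = "run"
    sweep_only: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path / generator must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            if "year_range" in gen:
                gen["year_range"] = tuple(gen["year_range"])
            gen = GeneratorConfig(**gen)
        return cls(generator=gen, **raw)


@dataclass
class PipelineResult:
    """Handles on the in-memory objects of a finished run."""

    out_dir: Path
    metadata: dict
    vectors: dict | None = None
    matrix: Any = None
    network: Any = None
    lcc: Any = None
    partition: Any = None
    truth: Any = None
    recovery: dict | None = None


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with the failing stage
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute all stages in order, writing artifacts as each completes.

    A failure aborts with an error naming the stage; artifacts written by
    earlier stages are retained for debugging.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict[str, Any] = {"config": _config_dict(cfg)}

    # --- input ---------------------------------------------------------
    truth = None
    if cfg.generator is not None:
        records, truth = _stage("simulate")(generate_corpus)(cfg.generator)
        write_table(records_to_frame(records), out / "corpus.tsv")
        write_table(truth.to_frame(), out / "planted_topics.tsv")
    else:
        records = _stage("load")(load_corpus)(cfg.input_path)
    meta["n_records"] = len(records)
    logger.info("corpus: %d records", len(records))

    clean_cfg = CleanConfig.from_files(
        cfg.stopwords_path, cfg.commonwords_path, cfg.min_token_length
    )
    meta["lemmatizer"] = clean_cfg.lemmatizer_id

    # --- preprocessing -------------------------------------------------
    streams = _stage("preprocess")(preprocess_corpus)(records, cfg.field_name, clean_cfg)
    write_table(
        pd.DataFrame(
            [{"patent_id": pid, "tokens": " ".join(s.tokens)} for pid, s in streams.items()],
            columns=["patent_id", "tokens"],
        ),
        out / "tokens.tsv",
    )

    # --- vectorization -------------------------------------------------
    vectors = _stage("vectorize")(vec_mod.build_vectors)(streams, cfg.m)
    space = vec_mod.build_space(vectors.values())
    meta["n_vectorized"] = len(vectors)
    meta["n_excluded_empty"] = len(records) - len(vectors)
    meta["dimension_d"] = space.dimension
    write_table(vec_mod.vectors_to_frame(vectors), out / "vectors.tsv")
    logger.info("keyword space: d=%d over %d patents", space.dimension, len(vectors))

    matrix = _stage("similarity")(vec_mod.similarity_matrix)(vectors, space)
    sim_rows = []
    for a in range(len(matrix.ids)):
        for b in range(a + 1, len(matrix.ids)):
            sim_rows.append(
                {"id_i": matrix.ids[a], "id_j": matrix.ids[b], "c": round(float(matrix.values[a, b]), 12)}
            )
    write_table(pd.DataFrame(sim_rows, columns=["id_i", "id_j", "c"]), out / "similarity.tsv")

    # --- threshold sweep ----------------------------------------------
    sweep = _stage("sweep")(net_mod.lcc_sweep)(matrix, cfg.h_grid, cfg.include_zero_similarity)
    write_table(sweep, out / "lcc_sweep.tsv")
    if cfg.sweep_only:
        meta["stopped_after"] = "sweep"
        _write_meta(meta, out)
        return PipelineResult(out_dir=out, metadata=meta, vectors=vectors, matrix=matrix, truth=truth)

    h = cfg.h if cfg.h is not None else net_mod.choose_threshold(sweep)
    meta["H"] = h

    # --- network -------------------------------------------------------
    g = _stage("network")(net_mod.build_network)(matrix, h, cfg.include_zero_similarity)
    meta["n_edges"] = g.number_of_edges()
    edge_rows = [
        {"id_i": u, "id_j": v, "c": round(float(d.get("similarity", 1.0)), 12)}
        for u, v, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    write_table(pd.DataFrame(edge_rows, columns=["id_i", "id_j", "c"]), out / "edges.tsv")
    nx.write_graphml(g, out / "network.graphml")

    lcc = _stage("lcc")(net_mod.largest_connected_component)(g)
    meta["lcc_size"] = lcc.number_of_nodes()
    logger.info("network at H=%.3f: %d edges, LCC size %d", h, g.number_of_edges(), lcc.number_of_nodes())

    # --- degrees and exponent -----------------------------------------
    stats = _stage("degrees")(net_mod.degree_stats)(lcc, cfg.k_min, cfg.k_max)
    write_table(
        pd.DataFrame(
            [{"patent_id": pid, "k": k} for pid, k in sorted(stats.degrees.items(), key=lambda kv: str(kv[0]))],
            columns=["patent_id", "k"],
        ),
        out / "degrees.tsv",
    )
    if stats.fit is not None:
        import math

        meta["gamma"] = round(stats.fit.gamma, 6)
        meta["gamma_stderr"] = round(stats.fit.stderr, 6)
        if math.isfinite(stats.fit.ls_slope):
            meta["gamma_ls_slope"] = round(stats.fit.ls_slope, 6)
        meta["gamma_degenerate"] = stats.fit.degenerate

    # --- communities ---------------------------------------------------
    partition = _stage("communities")(comm_mod.louvain)(g, cfg.community_seed)
    meta["n_communities"] = partition.n_communities
    meta["modularity_Q"] = round(partition.q, 6)
    write_table(comm_mod.partition_to_frame(partition), out / "partition.tsv")
    profiles = comm_mod.community_keywords(partition, vectors, n=10)
    write_table(comm_mod.profiles_to_frame(profiles), out / "community_profiles.tsv")
    write_table(comm_mod.profiles_to_wide(profiles, n=5), out / "community_top5.tsv")
    logger.info("communities: %d, Q=%.4f", partition.n_communities, partition.q)

    recovery = None
    if truth is not None:
        recovery = evaluate_recovery(
            {pid: partition.membership[pid] for pid in partition.membership},
            truth,
        ) if set(partition.membership) == set(truth.topics) else None
        if recovery is not None:
            meta["recovery_nmi"] = round(recovery["nmi"], 6)
            meta["recovery_ari"] = round(recovery["ari"], 6)

    # --- trends --------------------------------------------------------
    lexicon = (
        trends_mod.DosageFormLexicon.from_tsv(cfg.lexicon_path)
        if cfg.lexicon_path
        else trends_mod.default_lexicon()
    )
    series = _stage("trends")(trends_mod.trend_series)(records, lexicon, clean_cfg)
    write_table(series.to_frame(), out / "trends_yearly.tsv")
    write_table(series.to_frame(cumulative=True), out / "trends_cumulative.tsv")
    write_table(series.totals_frame(), out / "trends_totals.tsv")

    _write_meta(meta, out)
    return PipelineResult(
        out_dir=out,
        metadata=meta,
        vectors=vectors,
        matrix=matrix,
        network=g,
        lcc=lcc,
        partition=partition,
        truth=truth,
        recovery=recovery,
    )


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.get("generator") is not None:
        d["generator"]["year_range"] = list(d["generator"]["year_range"])
        d["generator"]["form_term_rates"] = dict(d["generator"]["form_term_rates"])
    d["h_grid"] = [float(h) for h in d["h_grid"]]
    return d


def _write_meta(meta: dict, out: Path) -> None:
    try:
        from importlib.metadata import version

        meta["versions"] = {
            pkg: version(pkg) for pkg in ("patentscape", "numpy", "scipy", "pandas", "networkx")
        }
    except Exception:
        pass
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True), "utf-8")
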