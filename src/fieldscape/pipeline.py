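"""End-to-end pipeline orchestration.

Stages: ingest -> vocab -> fit -> bias -> trends -> landscape ->
citations (plus an optional up-front simulate stage).  Every stage
writes its artifacts plus a small manifest recording a hash of its
configuration and input files; re-running with an unchanged
configuration skips stages whose manifests still match.  A single
master seed is stretched into independent per-stage seeds by stable
hashing of the stage name, so adding a stage never perturbs the
randomness of earlier ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import citations as cit
from . import corpus_io, field_bias, landscape, lda, synthetic, trends

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; serialized verbatim into the output."""

    output_dir: str = "fieldscape-run"
    corpus_path: str | None = None
    refs_path: str | None = None
    simulate: bool = False
    # simulation
    sim_k: int = 10
    sim_vocab: int = 500
    sim_n_biased: int = 3
    sim_docs_base: int = 54
    sim_doc_length: float = 300.0
    sim_refs_per_doc: float = 30.0
    # vocabulary
    min_df: float = 0.001
    max_df: float = 0.80
    # model
    k: int = 10
    k_grid: list | None = None
    alpha: float | None = None
    beta: float = 0.01
    n_iter: int = 1500
    burn_in: int = 1000
    thin: int = 10
    # bias / trends
    tau: float = 0.05
    m_biased: int = 3
    quantile: float = 0.5
    bootstrap_B: int = 1000
    # landscape
    perplexity: float = 30.0
    grid_size: int = 200
    boundary_eps: float = float(np.log(1.5))
    master_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _file_sha(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_key(config: RunConfig, stage: str, inputs: list[Path]) -> str:
    payload = {
        "stage": stage,
        "config": dataclasses.asdict(config),
        "inputs": {str(p): _file_sha(p) for p in inputs if p.exists()},
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


class PipelineRun:
    """Executes stages in order, with manifest-based resumption."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(self.out / "config.yaml")
        self.skipped: list[str] = []
        self.executed: list[str] = []

    def _run_stage(self, stage: str, inputs: list[Path], outputs: list[Path], fn):
        manifest = self.out / f"manifest-{stage}.json"
        key = _manifest_key(self.config, stage, inputs)
        if manifest.exists() and all(p.exists() for p in outputs):
            if json.loads(manifest.read_text()).get("key") == key:
                logger.info("stage %s: up to date, skipped", stage)
                self.skipped.append(stage)
                return
        try:
            fn()
        except Exception as exc:  # halt with the stage name and cause
            raise StageError(stage, exc) from exc
        manifest.write_text(json.dumps(
            {"key": key, "seed": self.config.stage_seed(stage)}, indent=2))
        self.executed.append(stage)

    # ------------------------------------------------------------------

    def run(self) -> Path:
        cfg = self.config
        corpus_path = Path(cfg.corpus_path) if cfg.corpus_path else self.out / "corpus.jsonl"
        refs_path = Path(cfg.refs_path) if cfg.refs_path else self.out / "refs.csv"

        if cfg.simulate:
            def do_simulate():
                seed = cfg.stage_seed("simulate")
                truth = synthetic.make_truth(k=cfg.sim_k, V=cfg.sim_vocab,
                                             n_biased_per_field=cfg.sim_n_biased,
                                             seed=seed)
                corpus = synthetic.generate_corpus(
                    truth, docs_per_field_year_base=cfg.sim_docs_base,
                    doc_length_mean=cfg.sim_doc_length, seed=seed + 1)
                synthetic.generate_citations(
                    corpus, refs_per_doc_mean=cfg.sim_refs_per_doc, seed=seed + 2)
                corpus_io.write_corpus(corpus.documents, corpus_path)
                synthetic.references_frame(corpus.citations).to_csv(refs_path, index=False)
                synthetic.save_truth(truth, self.out / "truth")
            self._run_stage("simulate", [], [corpus_path, refs_path], do_simulate)

        state: dict = {}

        def do_ingest():
            state["docs"] = corpus_io.load_corpus(corpus_path)
            corpus_io.corpus_frame(state["docs"]).to_csv(self.out / "articles.csv", index=False)
            corpus_io.articles_per_year(state["docs"]).to_csv(
                self.out / "articles_per_year.csv", index=False)
        self._run_stage("ingest", [corpus_path], [self.out / "articles.csv"], do_ingest)
        if "docs" not in state:
            state["docs"] = corpus_io.load_corpus(corpus_path)

        def do_vocab():
            vocab = corpus_io.build_vocabulary(state["docs"], cfg.min_df, cfg.max_df)
            vocab.write_csv(self.out / "vocabulary.csv")
            X = corpus_io.vectorize(state["docs"], vocab)
            corpus_io.write_matrix(X, self.out / "doc_term.mtx")
            state["vocab"], state["X"] = vocab, X
        self._run_stage("vocab", [corpus_path], [self.out / "vocabulary.csv",
                                                 self.out / "doc_term.mtx"], do_vocab)
        if "X" not in state:
            state["vocab"] = corpus_io.Vocabulary.read_csv(self.out / "vocabulary.csv")
            state["X"] = corpus_io.read_matrix(self.out / "doc_term.mtx")

        def do_fit():
            seed = cfg.stage_seed("fit")
            k = cfg.k
            if cfg.k_grid:
                k, table = lda.select_k(state["X"], cfg.k_grid, n_iter=cfg.n_iter,
                                        burn_in=cfg.burn_in, thin=cfg.thin,
                                        alpha=cfg.alpha, beta=cfg.beta, seed=seed)
                table.to_csv(self.out / "coherence_by_k.csv", index=False)
            fit = lda.fit_lda(state["X"], k=k, alpha=cfg.alpha, beta=cfg.beta,
                              n_iter=cfg.n_iter, burn_in=cfg.burn_in,
                              thin=cfg.thin, seed=seed)
            np.save(self.out / "phi.npy", fit.components_)
            np.save(self.out / "theta.npy", fit.doc_topic_)
            tops = pd.DataFrame({
                "topic": range(k),
                "top_words": [" ".join(lda.top_words(fit, t, min(10, len(state["vocab"])),
                                                     state["vocab"].stems))
                              for t in range(k)],
            })
            tops.to_csv(self.out / "top_words.csv", index=False)
            with open(self.out / "model.yaml", "w") as fh:
                yaml.safe_dump({"k": k, "alpha": fit._effective_alpha(),
                                "beta": cfg.beta, "n_iter": cfg.n_iter,
                                "burn_in": cfg.burn_in, "thin": cfg.thin,
                                "seed": seed}, fh)
            state["fit"] = fit
        self._run_stage("fit", [self.out / "doc_term.mtx"],
                        [self.out / "phi.npy", self.out / "theta.npy"], do_fit)
        theta = state["fit"].doc_topic_ if "fit" in state else np.load(self.out / "theta.npy")
        docs = state["docs"]
        labels = np.array([d.field for d in docs])
        years = np.array([d.year for d in docs])

        def do_bias():
            table = field_bias.field_bias_table(theta, labels, tau=cfg.tau)
            table.to_csv(self.out / "field_bias.csv", index=False)
            eco_set, cons_set = field_bias.top_biased_topics(table, m=cfg.m_biased)
            eco_rr, cons_rr = field_bias.top_biased_topics(table, m=cfg.m_biased, method="rr")
            with open(self.out / "bias_sets.yaml", "w") as fh:
                yaml.safe_dump({"delta": {"ecology": sorted(int(t) for t in eco_set),
                                          "conservation": sorted(int(t) for t in cons_set)},
                                "rr": {"ecology": sorted(int(t) for t in eco_rr),
                                       "conservation": sorted(int(t) for t in cons_rr)}}, fh)
            state["bias_sets"] = (eco_set, cons_set)
        self._run_stage("bias", [self.out / "theta.npy"],
                        [self.out / "field_bias.csv", self.out / "bias_sets.yaml"], do_bias)
        if "bias_sets" not in state:
            with open(self.out / "bias_sets.yaml") as fh:
                sets = yaml.safe_load(fh)["delta"]
            state["bias_sets"] = (set(sets["ecology"]), set(sets["conservation"]))

        def do_trends():
            eco_set, cons_set = state["bias_sets"]
            seed = cfg.stage_seed("trends")
            qr = trends.bias_trend_quantreg(theta, labels, years, eco_set, cons_set,
                                            q=cfg.quantile, B=cfg.bootstrap_B, seed=seed)
            pd.DataFrame({"term": qr.params.index, "estimate": qr.params.values,
                          "se": qr.bse.values, "p": qr.pvalues.values}).to_csv(
                self.out / "quantreg.csv", index=False)
            about = field_bias.discretize(theta, cfg.tau)
            rows = []
            for name, tset in (("ecology_biased", eco_set), ("conservation_biased", cons_set)):
                counts = field_bias.count_about_articles(about, tset, years, labels)
                for f in ("ecology", "conservation"):
                    sub = counts[counts["field"] == f]
                    pf = trends.fit_polynomial_trends(sub["year"].values, sub["count"].values)
                    rows.append({"bias_set": name, "field": f,
                                 "chosen_order": pf.chosen_order,
                                 "peak_year": pf.peak_year,
                                 "slope": pf.coefficients[1]})
            pd.DataFrame(rows).to_csv(self.out / "poly_trends.csv", index=False)
            div = trends.diversity_series(about, years, labels, B=cfg.bootstrap_B,
                                          seed=seed + 1)
            div.to_csv(self.out / "diversity.csv", index=False)
        self._run_stage("trends", [self.out / "theta.npy", self.out / "bias_sets.yaml"],
                        [self.out / "quantreg.csv", self.out / "poly_trends.csv",
                         self.out / "diversity.csv"], do_trends)

        def do_landscape():
            seed = cfg.stage_seed("landscape")
            coords = landscape.embed_2d(theta, perplexity=cfg.perplexity, seed=seed)
            pd.DataFrame({"id": [d.id for d in docs], "x": coords[:, 0],
                          "y": coords[:, 1]}).to_csv(self.out / "coords.csv", index=False)
            extent = landscape.grid_extent(coords)
            g_eco = landscape.density_grid(coords, subset=labels == "ecology",
                                           G=cfg.grid_size, extent=extent)
            g_cons = landscape.density_grid(coords, subset=labels == "conservation",
                                            G=cfg.grid_size, extent=extent)
            np.save(self.out / "density_ecology.npy", g_eco.density)
            np.save(self.out / "density_conservation.npy", g_cons.density)
            with open(self.out / "extent.yaml", "w") as fh:
                yaml.safe_dump({"extent": [float(v) for v in extent],
                                "G": cfg.grid_size}, fh)
            landscape.field_boundary(g_eco, g_cons, eps=cfg.boundary_eps).to_csv(
                self.out / "boundary.csv", index=False)
            state["coords"] = coords
        self._run_stage("landscape", [self.out / "theta.npy"],
                        [self.out / "coords.csv", self.out / "boundary.csv"], do_landscape)

        if refs_path.exists():
            def do_citations():
                refs = pd.read_csv(refs_path)
                records = cit.records_from_frame(refs)
                index = cit.CorpusIndex.build(
                    [d.id for d in docs],
                    dois=[f"10.5555/{d.id}" for d in docs],
                    titles=[d.title or "" for d in docs])
                resolved = cit.resolve_citations(records, index)
                edges = cit.citation_edges(resolved)
                edges.to_csv(self.out / "citation_edges.csv", index=False)
                field_map = {d.id: d.field for d in docs}
                stats = cit.cross_field_stats(edges, field_map, n_references=len(records))
                with open(self.out / "citation_stats.yaml", "w") as fh:
                    yaml.safe_dump({
                        "n_references": stats.n_references,
                        "n_resolved": stats.n_resolved,
                        "resolved_fraction": float(stats.resolved_fraction),
                        "cross_total": stats.cross_total,
                        "row_percent": {
                            str(i): {str(c): float(v) for c, v in row.items()}
                            for i, row in stats.row_percent.iterrows()},
                    }, fh)
                weights = cit.cross_citation_weights(edges, field_map, [d.id for d in docs])
                weights.rename("cross_citations").to_csv(self.out / "citation_weights.csv")
            self._run_stage("citations", [refs_path],
                            [self.out / "citation_edges.csv",
                             self.out / "citation_stats.yaml"], do_citations)
        return self.out


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory."""
    return PipelineRun(config).run()
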