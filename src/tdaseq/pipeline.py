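"""End-to-end orchestration: scores -> Mapper -> PI -> GSS -> sensitivity.

The pipeline mirrors the analysis workflow: standardize each subject's
log2 expression profile under a fitted Gaussian mixture, build a Mapper
graph on the scores with a mean-correlation filter, assign position
indices on the strand, export the PI subgroups for external
differential-expression tooling, compute heat-kernel graphical subject
scores, and sweep Mapper parameters for empirical confidence intervals.
Every output table is stamped with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from tdaseq import gmm, io, mapper, pi as pimod, sensitivity, spectral, synthetic

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("tdaseq")


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run (YAML-serializable)."""

    matrix_path: str | None = None
    labels_path: str | None = None
    out_dir: str = "tdaseq_out"
    orientation: str = "genes_by_subjects"
    score_kind: str = "T0"
    assignment_mode: str = "hard"
    n_components: int = 2
    pseudo_count: float = 1.0
    b: int = 20
    p: float = 50.0
    epsilon: float | str = "auto"
    filter_kind: str = "mean_corr"
    linkage: str = "single"
    pi_fraction: float = 0.25
    weight_rule: str = "tumor_fraction"
    smoothing_alpha: float = 1.0
    t_rule: str | float = "auto"
    grid_b: tuple = ()
    grid_p: tuple = ()
    grid_eps: tuple = ()
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_b", "grid_p", "grid_eps"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key in ("grid_b", "grid_p", "grid_eps"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and
        logging excluded, so reruns into different directories stamp
        identically)."""
        data = asdict(self)
        data.pop("out_dir", None)
        data.pop("log_level", None)
        payload = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.config_hash()
    df["seed"] = config.seed
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle to ``out_dir``.

    Returns a dict of the in-memory results (scores, graph, assignment,
    gss, ensemble, ci reports) plus the paths written. Identical configs
    and inputs produce byte-identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if config.matrix_path is None:
            raise ValueError("matrix_path is required (use the simulate "
                             "subcommand to create a cohort first)")
        fpkm = io.read_expression_matrix(config.matrix_path, config.orientation)
        labels = io.read_labels(config.labels_path) if config.labels_path else None
        log.info("matrix: %d genes x %d subjects", *fpkm.shape)

        stage = "scores"
        scores, fits, gof = gmm.compute_score_matrix(
            fpkm,
            kind=config.score_kind,
            mode=config.assignment_mode,
            n_components=config.n_components,
            pseudo_count=config.pseudo_count,
            seed=config.seed,
        )
        io.write_table(_stamp(scores, config), out / "scores.tsv",
                       index_label="subject_id")
        io.write_table(_stamp(gof, config), out / "gof.tsv")

        stage = "mapper"
        X = scores.to_numpy()
        subject_ids = list(scores.index)
        filter_values = mapper.compute_filter(X, config.filter_kind, subject_ids)
        eps = config.epsilon
        if eps == "auto":
            eps = synthetic.suggest_epsilon(X)
            log.info("auto epsilon = %.4g", eps)
        params = mapper.MapperParams(
            b=config.b, p=config.p, epsilon=float(eps),
            filter_kind=config.filter_kind, linkage=config.linkage,
        )
        graph = mapper.build_mapper(X, params, subject_ids, filter_values)
        log.info("mapper: b=%d p=%g eps=%.4g -> %d nodes / %d edges",
                 params.b, params.p, params.epsilon, graph.n_nodes,
                 len(graph.edges))
        graph.write_graphml(out / "graph.graphml", labels)
        graph.write_json(out / "graph.json", labels)
        io.write_table(
            _stamp(pd.DataFrame({"filter": pd.Series(graph.filter_values)}),
                   config),
            out / "filter.tsv", index_label="subject_id",
        )

        stage = "position_index"
        assignment = pimod.assign_position_index(graph, config.pi_fraction)
        pi_df = pd.DataFrame({"pi": assignment.values})
        pi_df["strandlike"] = assignment.strandlike
        io.write_table(_stamp(pi_df, config), out / "pi.tsv",
                       index_label="subject_id")
        if labels is not None:
            pimod.export_pi_groups(assignment, labels, out / "pi_groups")

        results: dict = {
            "scores": scores, "fits": fits, "gof": gof, "graph": graph,
            "assignment": assignment, "epsilon": float(eps), "out_dir": out,
        }

        if labels is not None:
            stage = "gss"
            gss = spectral.compute_gss(
                graph, labels, config.t_rule,
                config.smoothing_alpha, config.weight_rule,
            )
            gss_df = pd.DataFrame({"gss": gss.scores})
            for key in ("b", "p", "epsilon"):
                gss_df[key] = gss.provenance[key]
            gss_df["t"] = gss.t if isinstance(gss.t, float) else "per-component"
            io.write_table(_stamp(gss_df, config), out / "gss.tsv",
                           index_label="subject_id")
            results["gss"] = gss

            stage = "sensitivity"
            if config.grid_b and config.grid_p and config.grid_eps:
                grid = sensitivity.ParameterGrid(
                    tuple(config.grid_b), tuple(config.grid_p),
                    tuple(float(e) for e in config.grid_eps),
                )
                ensemble = sensitivity.sweep(
                    scores, labels, grid, t_rule=config.t_rule,
                    filter_kind=config.filter_kind, linkage=config.linkage,
                    smoothing_alpha=config.smoothing_alpha,
                    weight_rule=config.weight_rule,
                )
                io.write_table(_stamp(ensemble.table, config),
                               out / "gss_ensemble.tsv")
                ci_frames = []
                for vary, fixed in _ci_panels(grid):
                    try:
                        rep = sensitivity.empirical_ci(ensemble, vary, fixed)
                    except ValueError:
                        continue
                    tbl = rep.table.reset_index()
                    tbl["vary"] = vary
                    for k, v in fixed.items():
                        tbl[f"fixed_{k}"] = v
                    ci_frames.append(tbl)
                if ci_frames:
                    io.write_table(
                        _stamp(pd.concat(ci_frames, ignore_index=True), config),
                        out / "gss_ci.tsv",
                    )
                results["ensemble"] = ensemble
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    log.info("wrote artifact bundle to %s (config %s)", out,
             config.config_hash())
    return results


def _ci_panels(grid: sensitivity.ParameterGrid):
    """One (vary, fixed) pair per combination of the two held axes."""
    for vary in ("b", "p", "epsilon"):
        axes = {"b": grid.b_values, "p": grid.p_values,
                "epsilon": grid.eps_values}
        held = [a for a in axes if a != vary]
        for v0 in axes[held[0]]:
            for v1 in axes[held[1]]:
                yield vary, {held[0]: v0, held[1]: v1}
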