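"""End-to-end pipeline orchestration and tabular reporting.

``run_pipeline`` chains the stages — build (LCC extraction), per-node
topology profile, community detection + enrichment, target knockout, and
candidate prediction — writing one TSV/JSON artifact per stage plus a
manifest.  Every output starts with ``#`` header lines naming the seed and
the configuration hash, and all content is deterministic for a fixed
config + seed, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .community import detect_communities
from .enrichment import community_enrichment, coreness_enrichment
from .knockout import knockout_experiment
from .network_io import (
    assign_labels,
    largest_connected_component,
    parse_edge_list,
    read_feature_table,
    read_labels,
)
from .prediction import (
    cross_validate,
    naive_bayes_target_score,
    predict_candidates,
    select_negative_set,
    train_margin_classifier,
)
from .topology import coreness_map, profile_table

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat configuration of a pipeline run."""

    edges: str
    targets: str
    featured: str | None = None
    features: str | None = None
    out_dir: str = "targetnet_out"
    seed: int = 0
    min_community_size: int = 50
    knockout_metrics: tuple = ("degree", "eccentricity")
    negative_fraction: float = 0.5
    folds: int = 10

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file (# comments allowed)."""
        raw: dict = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line: {line!r}")
                key, value = (s.strip() for s in line.split("=", 1))
                raw[key] = value
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw.pop(f.name)
            if f.name == "knockout_metrics":
                kwargs[f.name] = tuple(s.strip() for s in v.split(",") if s.strip())
            elif f.type.startswith("int"):
                kwargs[f.name] = int(v)
            elif f.type.startswith("float"):
                kwargs[f.name] = float(v)
            else:
                kwargs[f.name] = v
        if raw:
            raise ValueError(f"unknown config key(s): {sorted(raw)}")
        return cls(**kwargs)

    def hash(self) -> str:
        """Digest of the analysis-relevant settings (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> int:
    """Run all stages; return 0 on success, 1 on stage failure.

    On failure a ``FAILED`` marker naming the stage is left in the output
    directory alongside whatever artifacts completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    head = [f"seed: {config.seed}", f"config: {config.hash()}"]
    manifest: dict = {
        "targetnet_version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "inputs": {},
        "outputs": [],
        "stages": {},
    }
    stage = "build"
    try:
        for key in ("edges", "targets", "featured", "features"):
            p = getattr(config, key)
            if p:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input path does not exist: {p}")
                manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

        # --- build ---------------------------------------------------
        full, load_report = parse_edge_list(config.edges)
        net = largest_connected_component(full)
        targets = read_labels(config.targets)
        featured = read_labels(config.featured) if config.featured else set()
        labels = assign_labels(net, targets, featured)
        stats = pd.DataFrame(
            [
                {
                    "nodes_total": full.number_of_nodes(),
                    "edges_total": full.number_of_edges(),
                    "nodes_lcc": net.number_of_nodes(),
                    "edges_lcc": net.number_of_edges(),
                    "n_targets": labels.n_targets,
                    "n_pt1": len(labels.pending_featured),
                    "n_pt2": len(labels.pending_unfeatured),
                    "dr": labels.dr,
                    "pr": labels.pr,
                    "lines_skipped": load_report.n_skipped,
                }
            ]
        )
        _write_tsv(stats, out / "network_stats.tsv", head)
        manifest["outputs"].append("network_stats.tsv")
        manifest["stages"][stage] = "ok"

        # --- communities ---------------------------------------------
        stage = "communities"
        part = detect_communities(
            net, seed=config.seed, min_report_size=config.min_community_size
        )
        comm_df = pd.DataFrame(
            {"community": [part.assignment[v] for v in sorted(net.nodes(), key=str)]},
            index=pd.Index(sorted(net.nodes(), key=str), name="id"),
        )
        _write_tsv(
            comm_df,
            out / "communities.tsv",
            head + [f"q: {part.q:.10g}", f"n_communities: {part.n_communities}",
                    f"main_communities: {','.join(map(str, part.main_communities))}"],
        )
        manifest["outputs"].append("communities.tsv")
        manifest["stages"][stage] = "ok"

        # --- profile -------------------------------------------------
        stage = "profile"
        profile = profile_table(net, labels=labels, partition=part.assignment)
        _write_tsv(profile, out / "profile.tsv", head)
        manifest["outputs"].append("profile.tsv")
        manifest["stages"][stage] = "ok"

        # --- enrichment ----------------------------------------------
        stage = "enrichment"
        comm_enrich = community_enrichment(part, labels)
        core_enrich = coreness_enrichment(coreness_map(net), labels)
        _write_tsv(comm_enrich, out / "community_enrichment.tsv", head)
        _write_tsv(core_enrich, out / "coreness_enrichment.tsv", head)
        manifest["outputs"] += ["community_enrichment.tsv", "coreness_enrichment.tsv"]
        manifest["stages"][stage] = "ok"

        # --- knockout ------------------------------------------------
        stage = "knockout"
        ko = knockout_experiment(net, labels, metrics=config.knockout_metrics)
        ko_df = pd.DataFrame([dataclasses.asdict(r) for r in ko.values()])
        ko_df = ko_df.set_index("metric")
        _write_tsv(ko_df, out / "knockout.tsv", head)
        manifest["outputs"].append("knockout.tsv")
        manifest["stages"][stage] = "ok"

        # --- prediction ----------------------------------------------
        stage = "prediction"
        if not config.features:
            manifest["stages"][stage] = "skipped: no feature table configured"
        elif not labels.pending_featured:
            manifest["stages"][stage] = "skipped: no featured pending proteins (PT1)"
        else:
            feats, _rep = read_feature_table(config.features)
            scores = naive_bayes_target_score(
                profile[["community", "coreness"]], labels
            )
            selection = select_negative_set(scores, fraction=config.negative_fraction)
            with open(out / "negatives.txt", "w", encoding="utf-8") as fh:
                for line in head:
                    fh.write(f"# {line}\n")
                fh.write("\n".join(selection.negatives) + "\n")
            pos_ids = sorted(labels.targets & set(feats.index))
            neg_ids = sorted(set(selection.negatives) & set(feats.index))
            x_pos, x_neg = feats.loc[pos_ids], feats.loc[neg_ids]
            cv = cross_validate(
                x_pos, x_neg, folds=config.folds, seed=config.seed
            )
            model = train_margin_classifier(x_pos, x_neg, seed=config.seed)
            cand_ids = sorted(
                (set(labels.pending_featured) & set(feats.index)) - set(neg_ids)
            )
            candidates = predict_candidates(model, feats.loc[cand_ids])
            report = {
                "seed": config.seed,
                "config": config.hash(),
                "n_positives": len(pos_ids),
                "n_negatives": len(neg_ids),
                "confusion": {"tp": cv.tp, "fp": cv.fp, "tn": cv.tn, "fn": cv.fn},
                "accuracy": cv.accuracy,
                "ppv": cv.ppv,
                "npv": cv.npv,
                "n_candidates": len(candidates),
            }
            with open(out / "prediction.json", "w", encoding="utf-8") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")
            cand_df = pd.DataFrame(
                {"candidate": list(candidates)}
            ).set_index("candidate")
            _write_tsv(cand_df, out / "candidates.tsv", head)
            manifest["outputs"] += ["negatives.txt", "prediction.json",
                                    "candidates.tsv"]
            manifest["stages"][stage] = "ok"
    except Exception as exc:  # partial outputs retained, marker written
        (out / "FAILED").write_text(
            f"stage: {stage}\nerror: {exc}\n\n{traceback.format_exc()}"
        )
        manifest["stages"][stage] = f"failed: {exc}"
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return 1
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return 0
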