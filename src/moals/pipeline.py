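"""End-to-end pipeline: gene selection -> burden -> training -> evaluation.

Stages read and write plain TSV/JSON artifacts; a content-hash cache skips
a stage when its inputs and configuration are unchanged from the previous
run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from . import evaluation, pathway_feature_selection
from .io_formats import (OmicsBlock, SampleTable, read_expression_matrix, read_gmt,
                         read_sample_table, write_expression_matrix)
from .multitask_training import MoalsNetwork

log = logging.getLogger("moals")


def _content_hash(paths: Sequence[Path], config: dict) -> str:
    h = hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode())
    for p in sorted(map(Path, paths)):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _cached(stage_dir: Path, stamp: str, outputs: Sequence[str]) -> bool:
    stamp_file = stage_dir / ".stamp"
    if not stamp_file.exists() or stamp_file.read_text() != stamp:
        return False
    return all((stage_dir / o).exists() for o in outputs)


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run select-genes -> train -> evaluate from a resolved config dict.

    Expected keys: paths ``expression``, ``burden``, ``samples``, ``gmt``;
    sub-configs ``selection`` (n_clusters, fuzziness, fdr_cutoff,
    target_sets), ``model`` (MoalsNetwork keyword arguments) and
    ``evaluation`` (k); global ``seed``. Artifacts and a resolved-config
    snapshot land under ``out_dir``; stages are cached by content hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config, indent=2, default=str))
    seed = int(config.get("seed", 0))

    expression = read_expression_matrix(config["expression"],
                                        orientation=config.get("orientation",
                                                               "genes_in_rows"))
    burden = read_expression_matrix(config["burden"],
                                    orientation=config.get("orientation",
                                                           "genes_in_rows"),
                                    name="burden")
    samples = read_sample_table(config["samples"])
    expression = expression.reindex_samples(samples.samples)
    burden = burden.reindex_samples(samples.samples)

    # --- stage: gene selection
    sel_cfg = dict(config.get("selection", {}))
    sel_dir = out / "select_genes"
    sel_dir.mkdir(exist_ok=True)
    stamp = _content_hash([Path(config["expression"]), Path(config["gmt"])],
                          {"selection": sel_cfg, "seed": seed})
    if sel_cfg.get("skip"):
        selected = list(expression.features)
        log.info("gene selection skipped by config; using all %d genes", len(selected))
    elif _cached(sel_dir, stamp, ["selected_genes.txt"]):
        selected = (sel_dir / "selected_genes.txt").read_text().split()
        log.info("gene selection: cache hit (%d genes)", len(selected))
    else:
        gene_sets = read_gmt(config["gmt"])
        selected, enrichment, _ = pathway_feature_selection.select_genes(
            expression, gene_sets,
            target_set_names=sel_cfg.get("target_sets", gene_sets.names()),
            n_clusters=sel_cfg.get("n_clusters", 8),
            fuzziness=sel_cfg.get("fuzziness", 2.0),
            fdr_cutoff=sel_cfg.get("fdr_cutoff", 0.05),
            seed=seed)
        (sel_dir / "selected_genes.txt").write_text("\n".join(selected) + "\n")
        enrichment.to_csv(sel_dir / "enrichment.tsv", sep="\t", index=False)
        (sel_dir / ".stamp").write_text(stamp)
        log.info("gene selection: %d of %d genes", len(selected),
                 len(expression.features))
    if not selected:
        raise RuntimeError("gene selection returned an empty list; "
                           "lower fdr_cutoff strictness or skip selection")
    expr_selected = expression.subset_features(selected)
    write_expression_matrix(expr_selected, out / "selected_expression.tsv")

    # --- stage: cross-validated training + evaluation
    eval_cfg = dict(config.get("evaluation", {}))
    model_cfg = dict(config.get("model", {}))
    report = evaluation.cross_validate([expr_selected, burden], samples,
                                       k=eval_cfg.get("k", 5), seed=seed,
                                       model_kwargs=model_cfg)
    report["fold_table"].to_csv(out / "fold_metrics.tsv", sep="\t", index=False)
    (out / "metrics.json").write_text(json.dumps(report["pooled"], indent=2))

    # --- stage: final model on all samples
    model = MoalsNetwork(random_state=seed, **model_cfg)
    model.fit([expr_selected, burden], samples)
    model.save(out / "model")
    return report
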