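"""End-to-end orchestration: config, stages, manifest, logging.

``run_full_pipeline`` executes matrix assembly, the prokaryotic filter,
Dollo reconstruction, retention tables for every configured
(origin, target) clade pair, lost-domain background summaries, and the
completeness report, writing every artifact plus a reproducibility
manifest (input checksums, config echo, package version, seed) into the
output directory. Outputs are a pure function of (inputs, config);
reruns are byte-identical apart from nothing — no timestamps are
embedded in data files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .completeness import read_completeness_tsv, write_completeness_report
from .dollo import reconstruct_all, write_reconstruction
from .matrix import (
    PresenceMatrix,
    build_matrix,
    filter_prokaryotic,
    read_matrix_tsv,
    read_pfamscan,
    read_prevalence_tsv,
    write_matrix_tsv,
)
from .retention import (
    count_above_threshold,
    lost_domain_retention_summary,
    retention_for_origin,
    write_retention_tsv,
)
from .tree import read_clade_tsv, read_clade_yaml, read_newick, resolve_clades

__all__ = ["RunConfig", "PipelineError", "run_full_pipeline"]

logger = logging.getLogger("domevol")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    Exactly one of ``annotations_dir`` (directory of ``<taxon>.pfam.tsv``
    files) or ``matrix_path`` (pre-built matrix TSV) must be given.
    ``retention_pairs`` lists (origin clade, target clade) name pairs;
    ``lost_background`` maps a clade name (whose resolved stem branch is
    inspected for losses) to the clade name providing background tips.
    """

    tree_path: str
    annotations_dir: str | None = None
    matrix_path: str | None = None
    prevalence_path: str | None = None
    clades_path: str | None = None
    completeness_path: str | None = None
    out_dir: str = "domevol_out"
    prokaryotic_threshold: float = 0.95
    retention_threshold_strict: float = 0.70
    retention_threshold_half: float = 0.50
    significant_only: bool = True
    evalue_max: float | None = None
    excluded_taxa: tuple[str, ...] = ()
    retention_pairs: tuple[tuple[str, str], ...] = ()
    lost_background: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.annotations_dir is None) == (self.matrix_path is None):
            raise ValueError(
                "exactly one of annotations_dir or matrix_path is required"
            )
        for name in (
            "prokaryotic_threshold",
            "retention_threshold_strict",
            "retention_threshold_half",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        if "retention_pairs" in data:
            data["retention_pairs"] = tuple(
                (str(a), str(b)) for a, b in data["retention_pairs"]
            )
        if "lost_background" in data:
            data["lost_background"] = tuple(
                (str(a), str(b)) for a, b in data["lost_background"]
            )
        if "excluded_taxa" in data:
            data["excluded_taxa"] = tuple(map(str, data["excluded_taxa"]))
        return cls(**data)

    def validate_paths(self) -> None:
        for label, p in (
            ("tree_path", self.tree_path),
            ("annotations_dir", self.annotations_dir),
            ("matrix_path", self.matrix_path),
            ("prevalence_path", self.prevalence_path),
            ("clades_path", self.clades_path),
            ("completeness_path", self.completeness_path),
        ):
            if p is not None and not Path(p).exists():
                raise PipelineError("validate", f"{label} does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_pipeline(config: RunConfig) -> Path:
    """Run every configured stage; returns the artifact directory.

    Any stage error is re-raised as :class:`PipelineError` naming the
    stage. A per-stage log (``pipeline.log``) and a manifest
    (``manifest.json``) are always written on success.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    inputs: dict[str, str] = {}
    try:
        # -- stage: tree ------------------------------------------------------
        try:
            tree = read_newick(config.tree_path)
            inputs["tree"] = config.tree_path
            logger.info(
                "tree: %d tips, %d internal nodes",
                len(tree.tips), len(tree.internal_nodes),
            )
        except Exception as exc:
            raise PipelineError("tree", str(exc)) from exc

        # -- stage: matrix ----------------------------------------------------
        try:
            if config.matrix_path is not None:
                matrix = read_matrix_tsv(config.matrix_path)
                inputs["matrix"] = config.matrix_path
            else:
                ann_dir = Path(config.annotations_dir)
                annotations = {}
                for p in sorted(ann_dir.glob("*.pfam.tsv")):
                    taxon = p.name[: -len(".pfam.tsv")]
                    annotations[taxon] = read_pfamscan(p)
                    inputs[f"annotation:{taxon}"] = str(p)
                if not annotations:
                    raise ValueError(
                        f"no *.pfam.tsv files in {ann_dir}"
                    )
                matrix = build_matrix(
                    annotations,
                    significant_only=config.significant_only,
                    evalue_max=config.evalue_max,
                )
            logger.info(
                "matrix: %d taxa x %d domains",
                len(matrix.taxa), len(matrix.domains),
            )
            write_matrix_tsv(matrix, out / "matrix_raw.tsv")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("matrix", str(exc)) from exc

        # -- stage: filter ----------------------------------------------------
        removed: list[str] = []
        if config.prevalence_path is not None:
            try:
                prevalence = read_prevalence_tsv(config.prevalence_path)
                inputs["prevalence"] = config.prevalence_path
                matrix, removed = filter_prokaryotic(
                    matrix, prevalence, config.prokaryotic_threshold
                )
                logger.info(
                    "filter: removed %d prokaryote-prevalent domains "
                    "(threshold %.2f), %d retained",
                    len(removed), config.prokaryotic_threshold,
                    len(matrix.domains),
                )
                (out / "removed_domains.txt").write_text(
                    "".join(f"{d}\n" for d in removed)
                )
            except Exception as exc:
                raise PipelineError("filter", str(exc)) from exc
        write_matrix_tsv(matrix, out / "matrix_filtered.tsv")

        # -- stage: reconstruct -----------------------------------------------
        try:
            reconstruction = reconstruct_all(tree, matrix)
            summary = reconstruction.summary
            logger.info(
                "reconstruct: %d domains, %d skipped (all-absent)",
                len(reconstruction.histories), len(reconstruction.skipped),
            )
            for node in tree.internal_nodes:
                if summary.gains[node] or summary.losses[node]:
                    logger.info(
                        "reconstruct: node %s: %d gains, %d losses, "
                        "content %d",
                        tree.label_of(node), summary.gains[node],
                        summary.losses[node], summary.content[node],
                    )
            write_reconstruction(reconstruction, out / "reconstruction")
        except Exception as exc:
            raise PipelineError("reconstruct", str(exc)) from exc

        # -- stage: retention ---------------------------------------------------
        clades = {}
        if config.clades_path is not None:
            try:
                path = Path(config.clades_path)
                defs = (
                    read_clade_yaml(path)
                    if path.suffix in (".yml", ".yaml")
                    else read_clade_tsv(path)
                )
                inputs["clades"] = str(path)
                resolved = resolve_clades(tree, defs)
                clades = {c.name: c for c in resolved}
                logger.info("clades: resolved %d definitions", len(clades))
            except Exception as exc:
                raise PipelineError("clades", str(exc)) from exc
            try:
                ret_dir = out / "retention"
                ret_dir.mkdir(exist_ok=True)
                counts_summary = {}
                for origin_name, target_name in config.retention_pairs:
                    origin = clades[origin_name]
                    target = clades[target_name]
                    table = retention_for_origin(
                        matrix, reconstruction, origin, target,
                        config.excluded_taxa,
                    )
                    write_retention_tsv(
                        table,
                        ret_dir / f"retention_{origin_name}_in_{target_name}.tsv",
                    )
                    n_strict = count_above_threshold(
                        table, config.retention_threshold_strict, strict=True
                    )
                    n_half = count_above_threshold(
                        table, config.retention_threshold_half, strict=False
                    )
                    counts_summary[f"{origin_name}_in_{target_name}"] = {
                        "domains": len(table),
                        f"over_{config.retention_threshold_strict:.0%}": n_strict,
                        "half_or_more": n_half,
                    }
                    logger.info(
                        "retention: %d domains gained at %s; %d retained "
                        ">%.0f%% in %s, %d in half or more",
                        len(table), origin_name, n_strict,
                        100 * config.retention_threshold_strict,
                        target_name, n_half,
                    )
                for lost_name, background_name in config.lost_background:
                    lost_node = clades[lost_name].resolved_node
                    background = clades[background_name]
                    median_p, n_half, table = lost_domain_retention_summary(
                        matrix, reconstruction, lost_node,
                        background.member_tips, config.excluded_taxa,
                    )
                    write_retention_tsv(
                        table,
                        ret_dir / f"lost_at_{lost_name}_in_{background_name}.tsv",
                    )
                    counts_summary[f"lost_at_{lost_name}"] = {
                        "domains": len(table),
                        "median_retention": (
                            None if median_p != median_p else median_p
                        ),
                        "half_or_more": n_half,
                    }
                    logger.info(
                        "retention: %d domains lost at %s stem; median "
                        "background retention %.3f, %d in half or more",
                        len(table), lost_name, median_p, n_half,
                    )
                (ret_dir / "summary.json").write_text(
                    json.dumps(counts_summary, indent=2, sort_keys=True) + "\n"
                )
            except Exception as exc:
                raise PipelineError("retention", str(exc)) from exc

        # -- stage: completeness ----------------------------------------------
        if config.completeness_path is not None:
            try:
                records = read_completeness_tsv(config.completeness_path)
                inputs["completeness"] = config.completeness_path
                write_completeness_report(
                    records, out / "completeness_report.tsv"
                )
                logger.info(
                    "completeness: %d records extrapolated", len(records)
                )
            except Exception as exc:
                raise PipelineError("completeness", str(exc)) from exc

        # -- manifest -----------------------------------------------------------
        manifest = {
            "tool": "domevol",
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "input_sha256": {
                label: _sha256(Path(p)) for label, p in sorted(inputs.items())
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        logger.info("done: artifacts in %s", out)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
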