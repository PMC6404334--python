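"""Single-command pipeline: io -> normalize/DE -> enrichment -> clustering ->
projection -> reports, with a run manifest for reproducibility.

Each stage writes its table before the next begins, so a failed run keeps its
partial outputs.  With a fixed seed the whole run is deterministic: k-means
restarts and permutation streams all derive from the one seed (per gene set,
by hashing the seed with the term ID, so adding or removing terms does not
shift other terms' results).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .cluster import evaluate_terms, write_validity
from .de import call_de_genes, load_de_table, run_de, write_de_table
from .enrichment import enrich_all, significant_terms, write_enrichment
from .io import read_counts, read_gene_sets, read_sample_table
from .model import Config, Contrast, ValidationError
from .normalize import estimate_size_factors, normalize_log
from .projection import project_all, write_projection
from .viz import render_de_heatmap, render_hma, render_pca, render_term_scatterpages

logger = logging.getLogger("gsepd")


@dataclass
class RunSpec:
    """Everything a pipeline run needs: input paths, the contrast, and the
    analysis configuration."""

    counts: str
    samples: str
    gene_sets: str
    group_a: str
    group_b: str
    term_names: str | None = None
    de_table: str | None = None  # externally computed DE table (optional)
    config: Config = field(default_factory=Config)


_RUNSPEC_KEYS = {"counts", "samples", "gene_sets", "group_a", "group_b", "term_names", "de_table"}
_CONFIG_KEYS = {f.name for f in Config.__dataclass_fields__.values()}


def validate_config(path: str | Path) -> RunSpec:
    """Parse and validate a YAML config file into a RunSpec.

    All violations are aggregated into one human-readable report.  Unknown
    keys are rejected by name.
    """
    import yaml

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a key-value mapping")

    errors: list[str] = []
    unknown = sorted(set(raw) - _RUNSPEC_KEYS - _CONFIG_KEYS)
    if unknown:
        errors.append(f"unknown key(s): {unknown}")
    for req in ("counts", "samples", "gene_sets", "group_a", "group_b"):
        if req not in raw:
            errors.append(f"missing required key: {req}")
    cfg_kwargs = {k: raw[k] for k in _CONFIG_KEYS if k in raw}
    config = None
    try:
        config = Config(**cfg_kwargs)
    except (ValidationError, TypeError) as exc:
        errors.append(str(exc))
    if errors:
        raise ValidationError(f"{path}: invalid config:\n  - " + "\n  - ".join(errors))
    return RunSpec(
        counts=str(raw["counts"]),
        samples=str(raw["samples"]),
        gene_sets=str(raw["gene_sets"]),
        group_a=str(raw["group_a"]),
        group_b=str(raw["group_b"]),
        term_names=str(raw["term_names"]) if raw.get("term_names") else None,
        de_table=str(raw["de_table"]) if raw.get("de_table") else None,
        config=config,
    )


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(spec: RunSpec) -> dict:
    """Execute the full analysis; returns the result tables keyed by stage.

    Outputs land in spec.config.output_dir: DE_table.tsv, enrichment.tsv,
    validity.tsv, projection_scores.tsv, figures with their numeric sidecar
    tables, run.log, and run_manifest.json (written atomically at run end).
    """
    config = spec.config
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {},
        "stage_rows": {},
        "stage_seconds": {},
    }
    results: dict = {}
    try:
        # ---- io
        t0 = time.perf_counter()
        counts = read_counts(spec.counts)
        samples = read_sample_table(spec.samples, counts)
        contrast = Contrast(spec.group_a, spec.group_b)
        contrast.validate_against(samples)
        collection = read_gene_sets(spec.gene_sets, spec.term_names)
        collection = collection.intersect_with(counts.gene_ids)
        for key, p in (("counts", spec.counts), ("samples", spec.samples), ("gene_sets", spec.gene_sets)):
            manifest["inputs"][key] = {"path": str(p), "sha256": _checksum(p)}
        if spec.term_names:
            manifest["inputs"]["term_names"] = {"path": spec.term_names, "sha256": _checksum(spec.term_names)}
        manifest["stage_seconds"]["io"] = time.perf_counter() - t0
        logger.info(
            "loaded %d genes x %d samples, %d gene sets after intersection",
            counts.n_genes, counts.n_samples, len(collection),
        )

        # ---- normalize + DE
        t0 = time.perf_counter()
        size_factors = estimate_size_factors(counts)
        norm = normalize_log(counts, size_factors, config.pseudocount)
        if spec.de_table:
            de = load_de_table(spec.de_table, counts)
            manifest["inputs"]["de_table"] = {"path": spec.de_table, "sha256": _checksum(spec.de_table)}
        else:
            de = run_de(norm, samples, contrast)
        calls = call_de_genes(de, config.de_p_threshold, config.use_padj_de)
        write_de_table(de, calls, out_dir / "DE_table.tsv")
        manifest["stage_rows"]["de"] = len(de)
        manifest["stage_seconds"]["de"] = time.perf_counter() - t0
        logger.info(
            "DE: %d genes tested, %d significant (%d up, %d down)",
            len(de), len(calls["all"]), len(calls["up"]), len(calls["down"]),
        )
        results.update(counts=counts, samples=samples, contrast=contrast,
                       collection=collection, norm=norm, de=de, calls=calls)

        # ---- enrichment
        t0 = time.perf_counter()
        universe = de.loc[de["pvalue"].notna(), "gene_id"].tolist()
        enrichment = enrich_all(collection, calls, universe, config)
        write_enrichment(enrichment, out_dir / "enrichment.tsv")
        sig_terms = significant_terms(enrichment, config)
        manifest["stage_rows"]["enrichment"] = len(enrichment)
        manifest["stage_seconds"]["enrichment"] = time.perf_counter() - t0
        logger.info("enrichment: %d significant term(s) of %d", len(sig_terms), len(collection))
        results.update(enrichment=enrichment, significant_terms=sig_terms)

        # ---- clustering / validity
        t0 = time.perf_counter()
        validity = evaluate_terms(sig_terms, collection, norm, samples, contrast, config)
        write_validity(validity, out_dir / "validity.tsv")
        seg_terms = validity.loc[validity["segregates"], "term_id"].tolist()
        n_skipped = int((validity["skip_reason"] != "").sum())
        manifest["stage_rows"]["validity"] = len(validity)
        manifest["stage_seconds"]["validity"] = time.perf_counter() - t0
        logger.info(
            "validity: %d evaluated (%d size-filtered), %d segregating at p < %g",
            len(validity), n_skipped, len(seg_terms), config.vmeasure_p_threshold,
        )
        results.update(validity=validity, segregating_terms=seg_terms)

        # ---- projection
        t0 = time.perf_counter()
        scores = project_all(norm, seg_terms, collection, samples, contrast, config)
        write_projection(scores, out_dir / "projection_scores.tsv")
        manifest["stage_rows"]["projection"] = len(scores)
        manifest["stage_seconds"]["projection"] = time.perf_counter() - t0
        results.update(scores=scores)

        # ---- reports
        t0 = time.perf_counter()
        render_hma(scores, validity, samples, contrast, config, out_dir)
        for tid in seg_terms:
            genes = collection[tid].members & set(norm.index)
            if len(genes) >= 2:
                render_term_scatterpages(tid, norm, scores, collection, samples, contrast, config, out_dir)
        render_pca(norm, samples, contrast, config, out_dir)
        render_de_heatmap(norm, de, calls, samples, contrast, config, out_dir)
        manifest["stage_seconds"]["reports"] = time.perf_counter() - t0
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()

    tmp = out_dir / "run_manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    os.replace(tmp, out_dir / "run_manifest.json")
    results["manifest"] = manifest
    return results
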