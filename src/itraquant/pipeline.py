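"""End-to-end pipeline runner, run manifest and report builder.

One structured YAML/JSON config drives every stage: simulate (optional,
when no real PSM table is given) -> quantify -> qc -> stats -> diffexp ->
cluster -> report.  Stage outputs are TSV/JSON files in the run directory;
a manifest records the config snapshot, input digests, seed and stage
completion so deterministic stages can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexp import call_differential, cluster_profiles, de_union_profiles, summarize_de
from .quant import (
    Comparison,
    CorrectionMatrix,
    compute_protein_ratios,
    correct_isotope_impurities,
    filter_psms,
    read_psm_table,
    rollup_peptides,
)
from .simulate import SimConfig, generate_ground_truth, simulate_psm_table, write_fixture
from .stats import mixing_check, median_normalize, replicate_qc, significance_b

logger = logging.getLogger(__name__)

DEFAULT_COMPARISONS = [
    {"id": "MIIG_vs_GVO", "numerator": ["116"], "denominator": ["114", "115"]},
    {"id": "MIIG_vs_MIIB", "numerator": ["116"], "denominator": ["117"]},
]

FLOAT_FORMAT = "%.10g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _comparisons_from(config: dict) -> list[Comparison]:
    spec = config.get("comparisons", DEFAULT_COMPARISONS)
    return [
        Comparison(id=c["id"], numerator=tuple(c["numerator"]), denominator=tuple(c["denominator"]))
        for c in spec
    ]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: dict | str | Path, out: str | Path | None = None, seed: int | None = None) -> Path:
    """Execute the full pipeline described by ``config``; returns the run dir.

    The config either names input files (``inputs.psms``, optionally
    ``inputs.matrix``) or contains a ``simulate`` block of
    :class:`~itraquant.simulate.SimConfig` fields.  ``out`` and ``seed``
    override the config's values.  On a stage failure the partial run
    directory is marked with a ``.partial`` file and a
    :class:`StageError` is raised naming the stage.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    config = dict(config)
    if seed is not None:
        config["seed"] = int(seed)
    run_dir = Path(out if out is not None else config.get("out", "itraquant_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    partial = run_dir / ".partial"
    partial.write_text("run in progress\n")

    manifest: dict = {
        "tool": "itraquant",
        "version": __version__,
        "seed": config.get("seed"),
        "config": _jsonable(config),
        "inputs": {},
        "stages": [],
    }

    def done(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **info})
        logger.info("stage %s done: %s", stage, info)

    try:
        comparisons = _comparisons_from(config)

        # --- inputs or simulation -------------------------------------
        if "inputs" in config:
            psm_path = Path(config["inputs"]["psms"])
            if not psm_path.exists():
                raise FileNotFoundError(f"PSM table not found: {psm_path}")
            manifest["inputs"]["psms"] = {"path": str(psm_path), "sha256": _sha256(psm_path)}
            psms = read_psm_table(psm_path)
            matrix_path = config["inputs"].get("matrix")
            if matrix_path:
                matrix_path = Path(matrix_path)
                if not matrix_path.exists():
                    raise FileNotFoundError(f"correction matrix not found: {matrix_path}")
                manifest["inputs"]["matrix"] = {"path": str(matrix_path), "sha256": _sha256(matrix_path)}
                matrix = CorrectionMatrix.from_tsv(matrix_path)
            else:
                matrix = CorrectionMatrix.identity()
            done("inputs", n_psms=len(psms))
        else:
            sim_block = dict(config.get("simulate", {}))
            if "seed" not in sim_block and "seed" in config:
                sim_block["seed"] = int(config["seed"])
            if "impurity_matrix" in sim_block:
                sim_block["impurity_matrix"] = CorrectionMatrix(
                    np.asarray(sim_block["impurity_matrix"], float)
                )
            for key in ("peptides_per_protein_dist", "psms_per_peptide_dist",
                        "log2fc_magnitudes", "log2fc_weights"):
                if key in sim_block:
                    sim_block[key] = tuple(sim_block[key])
            sim_cfg = SimConfig(**sim_block)
            truth = generate_ground_truth(sim_cfg)
            psms = simulate_psm_table(truth, sim_cfg)
            write_fixture(truth, psms, run_dir, sim_cfg)
            matrix = sim_cfg.impurity_matrix
            done("simulate", n_proteins=sim_cfg.n_proteins, n_psms=len(psms))

        # --- quantify --------------------------------------------------
        filt = config.get("filter", {})
        psms, filter_report = filter_psms(
            psms,
            min_confidence=float(filt.get("min_confidence", 0.01)),
            require_complete=bool(filt.get("require_complete", True)),
        )
        psms = correct_isotope_impurities(psms, matrix)
        peptides = rollup_peptides(psms)
        proteins = compute_protein_ratios(
            peptides, comparisons,
            min_unique_for_quant=int(config.get("quant", {}).get("min_unique_for_quant", 1)),
        )
        if config.get("normalize", {}).get("median", False):
            for comp in comparisons:
                proteins = median_normalize(proteins, comp.id)
        _write_tsv(proteins, run_dir / "proteins.tsv")
        done("quantify", filter=filter_report, n_proteins=len(proteins))

        # --- qc --------------------------------------------------------
        qc_cfg = config.get("qc", {})
        pair = [str(c) for c in qc_cfg.get("replicate_pair", ["114", "115"])]
        qc = replicate_qc(proteins, pair[0], pair[1])
        (run_dir / "qc_report.json").write_text(json.dumps(qc.to_dict(), indent=2) + "\n")
        mix = mixing_check(proteins, str(qc_cfg.get("mixing_reference", "114")),
                           float(qc_cfg.get("mixing_tolerance", 0.5)))
        _write_tsv(mix, run_dir / "mixing.tsv")
        done("qc", sigma_log2=qc.sigma_log2, pearson_r2=qc.pearson_r2)

        # --- stats + diffexp -------------------------------------------
        stats_cfg = config.get("stats", {})
        de_cfg = config.get("diffexp", {})
        all_calls = []
        for comp in comparisons:
            sig = significance_b(
                proteins, comp.id,
                bin_size=int(stats_cfg.get("bin_size", 300)),
                two_sided=bool(stats_cfg.get("two_sided", False)),
            )
            _write_tsv(sig, run_dir / f"significance_{comp.id}.tsv")
            calls = call_differential(
                proteins, sig, comp.id,
                fc_up=float(de_cfg.get("fc_up", 2.0)),
                fc_down=float(de_cfg.get("fc_down", 0.5)),
                alpha=float(de_cfg.get("alpha", 0.05)),
                min_unique=int(de_cfg.get("min_unique", 2)),
            )
            all_calls.append(calls)
        calls = pd.concat(all_calls, ignore_index=True)
        summary = summarize_de(calls)
        _write_tsv(calls, run_dir / "de_calls.tsv")
        _write_tsv(summary, run_dir / "de_summary.tsv")
        done("diffexp", **{r["comparison"]: int(r["n_total"]) for _, r in summary.iterrows()})

        # --- cluster ---------------------------------------------------
        k = int(config.get("cluster", {}).get("k", 5))
        profiles = de_union_profiles(proteins, calls)
        if len(profiles) >= k and k >= 1:
            clusters = cluster_profiles(profiles, k=k)
            _write_tsv(clusters, run_dir / "clusters.tsv")
            done("cluster", n_proteins=len(clusters), k=k)
        else:
            logger.warning("cluster: only %d DE proteins, need >= k=%d; skipped", len(profiles), k)
            done("cluster", skipped=True, n_de=len(profiles))

        # --- report ----------------------------------------------------
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        build_report(run_dir)
        done("report")
    except Exception as exc:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise StageError(stage=f"after:{stage}", cause=exc) from exc

    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    partial.unlink(missing_ok=True)
    return run_dir


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def build_report(run_dir: str | Path) -> Path:
    """Assemble a markdown + JSON report from a run directory's stage files.

    Numbers are read back from the stage TSV/JSON outputs, never
    recomputed, so the report cannot drift from the files it summarises.
    Missing stages are listed as not run.
    """
    run_dir = Path(run_dir)
    report: dict = {"run_dir": str(run_dir), "version": __version__}
    lines = ["# itraquant run report", ""]

    de_path = run_dir / "de_summary.tsv"
    if de_path.exists():
        summary = pd.read_csv(de_path, sep="\t")
        report["de_summary"] = summary.to_dict(orient="records")
        lines += ["## Differential expression", "",
                  "| comparison | up | down | total |", "|---|---|---|---|"]
        for _, r in summary.iterrows():
            lines.append(f"| {r['comparison']} | {r['n_up']} | {r['n_down']} | {r['n_total']} |")
        lines.append("")
    else:
        report["de_summary"] = None
        lines += ["## Differential expression", "", "not run", ""]

    qc_path = run_dir / "qc_report.json"
    if qc_path.exists():
        qc = json.loads(qc_path.read_text())
        report["qc"] = {k: qc[k] for k in
                        ("channel_a", "channel_b", "n", "sigma_log2", "pearson_r2",
                         "regression_slope", "frac_within_30pct")}
        lines += ["## Replicate QC", "",
                  f"- channels {qc['channel_a']} vs {qc['channel_b']} over {qc['n']} proteins",
                  f"- sigma(log2 ratio) = {qc['sigma_log2']:.4f}",
                  f"- Pearson R^2 = {qc['pearson_r2']:.4f}, slope = {qc['regression_slope']:.4f}",
                  f"- fraction within 30% variation = {qc['frac_within_30pct']:.3f}", ""]
    else:
        report["qc"] = None
        lines += ["## Replicate QC", "", "not run", ""]

    cl_path = run_dir / "clusters.tsv"
    if cl_path.exists():
        clusters = pd.read_csv(cl_path, sep="\t")
        sizes = clusters.groupby("cluster").size().sort_index()
        report["cluster_sizes"] = {int(k): int(v) for k, v in sizes.items()}
        report["n_clustered"] = int(len(clusters))
        lines += ["## Expression clusters", "", "| cluster | size |", "|---|---|"]
        for c, s in sizes.items():
            lines.append(f"| {c} | {s} |")
        lines += [f"", f"{len(clusters)} proteins clustered", ""]
    else:
        report["cluster_sizes"] = None
        lines += ["## Expression clusters", "", "not run", ""]

    ov_path = run_dir / "overlap.json"
    report["overlap"] = json.loads(ov_path.read_text()) if ov_path.exists() else None

    rq_path = run_dir / "rq.tsv"
    if rq_path.exists():
        report["qpcr"] = pd.read_csv(rq_path, sep="\t").to_dict(orient="records")
    else:
        report["qpcr"] = None
        lines += ["## qPCR", "", "not run", ""]

    (run_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    md = run_dir / "report.md"
    md.write_text("\n".join(lines) + "\n")
    return md
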