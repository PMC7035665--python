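"""One-command cohort pipeline.

From a parameter file (key = value lines, or JSON by extension) pointing at
a model, a gene-expression matrix and an objective file, the pipeline
builds one context-specific submodel per sample (expression core calling +
fastcore extraction, realized as zero bounds on excluded reactions so
reaction indices stay aligned), then runs FVA, the four knockout screens
and optionally hit-and-run sampling on each, writing TSV tables and a JSON
manifest under the output directory (default ./out).

Failure policy: a stage failure aborts that sample, is recorded in the
manifest, and the remaining samples continue — a cohort run must not die on
one degenerate sample.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import io as fio
from .knockout import (
    LETHALITY_CUTOFF,
    double_gene_ko,
    double_met_ko,
    single_gene_ko,
    single_met_ko,
)
from .lp import fva
from .model import MetabolicModel
from .reconstruction import reconstruction_by_fastcore
from .sampler import achr_sample, generate_warmup, max_stoich_violation

__all__ = ["PipelineConfig", "RunOutputs", "load_config", "run_one_command"]

logger = logging.getLogger("fluxtk.pipeline")


@dataclass
class PipelineConfig:
    model_path: str
    expression_path: str
    objective_file_path: str
    expression_cutoff: float = 75.0
    n_cpu: int = 1
    constraints_path: Optional[str] = None
    lethality_cutoff: float = LETHALITY_CUTOFF
    output_dir: str = "./out"
    run_mcmc: bool = True
    n_points: int = 2000
    n_steps: int = 1000
    seed: int = 0
    fraction_of_optimum: float = 1.0

    def validate(self) -> None:
        for label, p in (
            ("model", self.model_path),
            ("expression matrix", self.expression_path),
            ("objective file", self.objective_file_path),
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.constraints_path and not Path(self.constraints_path).exists():
            raise FileNotFoundError(
                f"constraints file not found: {self.constraints_path}"
            )
        if self.n_cpu < 1:
            raise ValueError("n_cpu must be >= 1")


@dataclass
class RunOutputs:
    output_dir: Path
    manifest: dict
    files: List[Path] = field(default_factory=list)


_KEYMAP = {
    "expression": "expression_path",
    "expression_path": "expression_path",
    "objectives": "objective_file_path",
    "objective_file": "objective_file_path",
    "objective_file_path": "objective_file_path",
    "cutoff": "expression_cutoff",
    "expression_cutoff": "expression_cutoff",
    "ncpu": "n_cpu",
    "n_cpu": "n_cpu",
    "model": "model_path",
    "model_path": "model_path",
    "constraints": "constraints_path",
    "constraints_path": "constraints_path",
    "lethality_cutoff": "lethality_cutoff",
    "out": "output_dir",
    "output_dir": "output_dir",
    "run_mcmc": "run_mcmc",
    "n_points": "n_points",
    "n_steps": "n_steps",
    "seed": "seed",
    "fraction": "fraction_of_optimum",
    "fraction_of_optimum": "fraction_of_optimum",
}

_FLOATS = {"expression_cutoff", "lethality_cutoff", "fraction_of_optimum"}
_INTS = {"n_cpu", "n_points", "n_steps", "seed"}
_BOOLS = {"run_mcmc"}


def load_config(path) -> PipelineConfig:
    """Parse a parameter file: JSON if the extension is .json, otherwise
    ``key = value`` lines ('#' starts a comment)."""

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    raw: Dict[str, str] = {}
    if path.suffix.lower() == ".json":
        raw = {str(k): v for k, v in json.loads(path.read_text()).items()}
    else:
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(
                    f"{path}:{lineno}: expected 'key = value', got {line!r}"
                )
            key, val = (part.strip() for part in line.split("=", 1))
            raw[key] = val
    kwargs = {}
    for key, val in raw.items():
        norm = _KEYMAP.get(key.lower())
        if norm is None:
            raise ValueError(f"unknown parameter {key!r} in {path}")
        if norm in _FLOATS:
            val = float(val)
        elif norm in _INTS:
            val = int(val)
        elif norm in _BOOLS and isinstance(val, str):
            val = val.strip().lower() in ("1", "true", "yes", "on")
        kwargs[norm] = val
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_one_command(config: PipelineConfig) -> RunOutputs:
    """Execute the full per-sample protocol and write all outputs.

    Per sample column of the expression matrix: fastcore reconstruction ->
    submodel (excluded reactions zero-bounded) -> FVA -> single/double gene
    KO -> single/double metabolite KO -> (optional) ACHR sampling. Writes
    inclusion_matrix.tsv, fva.tsv, singleGeneKO.tsv, doubleGeneKO.tsv,
    singleMetKO.tsv, doubleMetKO.tsv, mcmc_samples/<sample>.tsv and
    manifest.json under the output directory.
    """

    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    stream = logging.StreamHandler(sys.stderr)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (handler, stream):
        h.setFormatter(fmt)
        logger.addHandler(h)
    logger.setLevel(logging.INFO)

    try:
        model = fio.read_model(config.model_path)
        expr = fio.read_expression_tsv(config.expression_path)
        objectives = fio.read_objective_file(config.objective_file_path)
        base_overrides = (
            fio.read_constraint_tsv(config.constraints_path)
            if config.constraints_path
            else {}
        )

        t0 = time.time()
        inclusion = reconstruction_by_fastcore(
            model.with_bounds(base_overrides) if base_overrides else model,
            expr,
            config.expression_cutoff,
        )
        logger.info(
            "reconstruction: %d samples in %.2fs", inclusion.shape[1], time.time() - t0
        )

        files: List[Path] = []
        manifest: dict = {
            "config": asdict(config),
            "model_id": model.id,
            "samples": {},
            "files": {},
        }
        inc_path = out_dir / "inclusion_matrix.tsv"
        inclusion.to_csv(inc_path, sep="\t")
        files.append(inc_path)

        fva_blocks, sko_blocks, dko_blocks, smko_blocks, dmko_blocks = (
            [], [], [], [], [],
        )
        mcmc_dir = out_dir / "mcmc_samples"
        for sample in inclusion.columns:
            keep = inclusion.index[inclusion[sample] == 1].tolist()
            overrides = dict(base_overrides)
            overrides.update(model.subnetwork_bounds(keep))
            sample_t0 = time.time()
            try:
                for obj in objectives:
                    res = fva(
                        model,
                        config.fraction_of_optimum,
                        workers=config.n_cpu,
                        bound_overrides=overrides,
                        objective=obj,
                    )
                    df = res.to_frame()
                    df.insert(0, "objective_id", obj)
                    df.insert(0, "sample", sample)
                    fva_blocks.append(df)
                logger.info("%s fva %.2fs", sample, time.time() - sample_t0)

                for blocks, fn in (
                    (sko_blocks, single_gene_ko),
                    (dko_blocks, double_gene_ko),
                    (smko_blocks, single_met_ko),
                    (dmko_blocks, double_met_ko),
                ):
                    t = time.time()
                    tables = fn(
                        model,
                        objectives,
                        workers=config.n_cpu,
                        lethality_cutoff=config.lethality_cutoff,
                        bound_overrides=overrides,
                    )
                    for table in tables:
                        df = table.to_frame()
                        df.insert(0, "objective_id", table.objective_id)
                        df.insert(0, "sample", sample)
                        blocks.append(df)
                    logger.info("%s %s %.2fs", sample, fn.__name__, time.time() - t)

                if config.run_mcmc:
                    t = time.time()
                    warm = generate_warmup(
                        model, seed=config.seed, bound_overrides=overrides
                    )
                    chain = achr_sample(
                        model,
                        warm,
                        n_points=config.n_points,
                        n_steps=config.n_steps,
                        seed=config.seed,
                        bound_overrides=overrides,
                    )
                    mcmc_dir.mkdir(exist_ok=True)
                    spath = mcmc_dir / f"{sample}.tsv"
                    pd.DataFrame(
                        chain.samples,
                        index=pd.Index(model.reaction_ids, name="reaction_id"),
                        columns=[f"s{i}" for i in range(chain.samples.shape[1])],
                    ).to_csv(spath, sep="\t")
                    meta = {
                        "n_points": config.n_points,
                        "n_steps": config.n_steps,
                        "seed": config.seed,
                        "max_stoich_violation": max_stoich_violation(
                            model, chain.samples
                        ),
                    }
                    jpath = mcmc_dir / f"{sample}.json"
                    jpath.write_text(json.dumps(meta, indent=1))
                    files.extend([spath, jpath])
                    logger.info("%s mcmc %.2fs", sample, time.time() - t)
                manifest["samples"][sample] = {"status": "ok"}
            except Exception as exc:  # per-sample isolation
                logger.error("%s failed: %s", sample, exc)
                manifest["samples"][sample] = {"status": "failed", "error": str(exc)}

        for name, blocks in (
            ("fva.tsv", fva_blocks),
            ("singleGeneKO.tsv", sko_blocks),
            ("doubleGeneKO.tsv", dko_blocks),
            ("singleMetKO.tsv", smko_blocks),
            ("doubleMetKO.tsv", dmko_blocks),
        ):
            path = out_dir / name
            if blocks:
                pd.concat(blocks, ignore_index=True).to_csv(path, sep="\t", index=False)
            else:
                path.write_text("")
            files.append(path)

        manifest["files"] = {str(p.relative_to(out_dir)): _sha256(p) for p in files}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        files.append(out_dir / "manifest.json")
        return RunOutputs(output_dir=out_dir, manifest=manifest, files=files)
    finally:
        logger.removeHandler(handler)
        logger.removeHandler(stream)
        handler.close()
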