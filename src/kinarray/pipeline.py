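"""End-to-end orchestration: simulate/load -> QC -> call -> score -> compare.

One :func:`run_all` call takes a :class:`RunConfig` and produces a fully
file-backed artifact directory: every stage writes its outputs as TSV/JSON
and the next stage could be re-run from those files alone. A run manifest
(config, seed, package version, input and output checksums) makes reruns
auditable: the same config and seed reproduce byte-identical outputs.

Seed policy: the single run seed is expanded into per-stage substreams
with a fixed counter scheme — ``SeedSequence(seed, spawn_key=(k,))`` with
k = 0 for simulation and k = 1 for the permutation test — so re-running a
stage in isolation agrees with the full run.
"""

from __future__ import annotations

import dataclasses
import glob as globmod
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .array_model import (
    ArrayLayout,
    ReplicateQuantification,
    StudyDesign,
    reaction_filename,
    read_layout,
    read_quantification,
    write_layout,
    write_profile,
    write_quantification,
)
from .calling import call_reaction, write_calls
from .qc import CorrelationReport, qc_gate, replicate_correlations
from .scoring import (
    DifferentialCategoryTable,
    category_fractions,
    differential_categories,
    markov_scores,
)
from .synthetic import GenerationConfig, simulate_study

__all__ = ["RunConfig", "RunResult", "QCGateFailure", "run_all", "load_run_config"]

_STAGE_SIMULATE = 0
_STAGE_PERMUTATION = 1


class QCGateFailure(RuntimeError):
    """Raised when replicate QC fails and no override was requested."""


def stage_seed(seed: int, stage: int) -> int:
    """Derive a deterministic per-stage integer seed (< 2**31)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on.

    Either ``layout``/``quant_glob`` point at existing files, or
    ``simulate`` carries a :class:`GenerationConfig` and the run generates
    its own inputs under ``outdir/inputs``.
    """

    outdir: str
    layout: str | None = None
    quant_glob: str | None = None
    simulate: GenerationConfig | None = None
    design: StudyDesign = field(default_factory=StudyDesign)
    qc_threshold: float = 0.85
    call_method: str = "mixture"
    call_threshold: float = 0.5
    zscore_k: float = 3.0
    tau: int = 4
    n_perm: int = 10_000
    seed: int = 0
    override_qc: bool = False

    def __post_init__(self) -> None:
        if self.simulate is None and (self.layout is None or self.quant_glob is None):
            raise ValueError(
                "config needs either simulate parameters or layout + quant_glob"
            )
        if not 0.0 < self.qc_threshold <= 1.0:
            raise ValueError("qc_threshold must be in (0, 1]")
        if not 0.0 <= self.call_threshold <= 1.0:
            raise ValueError("call_threshold must be in [0, 1]")
        if self.call_method not in ("mixture", "zscore"):
            raise ValueError(f"unknown call_method {self.call_method!r}")
        if not 1 <= self.tau <= self.design.R:
            raise ValueError(f"tau must be in 1..{self.design.R}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass(frozen=True)
class RunResult:
    outdir: Path
    qc_reports: dict[str, CorrelationReport]
    qc_passed: bool
    differential: DifferentialCategoryTable | None
    manifest_path: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_payload(config: RunConfig) -> dict:
    payload = dataclasses.asdict(config)
    if config.simulate is not None:
        sim = dataclasses.asdict(config.simulate)
        sim["activity_multipliers"] = {
            c: {
                cat: m
                for (cc, cat), m in config.simulate.activity_multipliers.items()
                if cc == c
            }
            for c in config.simulate.design.conditions
        }
        sim["design"] = dataclasses.asdict(config.simulate.design)
        sim["design"]["conditions"] = list(config.simulate.design.conditions)
        payload["simulate"] = sim
    payload["design"] = dataclasses.asdict(config.design)
    payload["design"]["conditions"] = list(config.design.conditions)
    return payload


def _resolve_inputs(
    config: RunConfig, outdir: Path
) -> tuple[ArrayLayout, list[ReplicateQuantification], list[Path]]:
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(
            config.simulate, seed=stage_seed(config.seed, _STAGE_SIMULATE)
        )
        layout, quants, truth = simulate_study(sim_cfg)
        inputs = outdir / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        layout_path = inputs / "layout.tsv"
        write_layout(layout_path, layout)
        paths = [layout_path]
        for q in quants:
            p = inputs / reaction_filename(*q.key)
            write_quantification(p, q)
            paths.append(p)
        truth.to_json(inputs / "truth.json")
        paths.append(inputs / "truth.json")
        return layout, quants, paths

    layout_path = Path(config.layout)
    layout = read_layout(layout_path)
    paths = [layout_path]
    quants = []
    files = sorted(globmod.glob(config.quant_glob))
    if not files:
        raise ValueError(f"quantification glob matched no files: {config.quant_glob}")
    for f in files:
        quants.append(read_quantification(f, layout))
        paths.append(Path(f))
    return layout, quants, paths


def run_all(config: RunConfig) -> RunResult:
    """Run the whole pipeline and write every artifact under ``outdir``.

    Raises :class:`QCGateFailure` (and writes no scoring outputs) when any
    condition fails replicate QC and ``override_qc`` is not set.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout, quants, input_paths = _resolve_inputs(config, outdir)

    by_condition: dict[str, list[ReplicateQuantification]] = {}
    for q in quants:
        by_condition.setdefault(q.condition, []).append(q)
    if len(by_condition) != 2:
        raise ValueError(
            f"expected exactly two conditions, found {sorted(by_condition)}"
        )
    conditions = [c for c in config.design.conditions if c in by_condition]
    if len(conditions) != 2:  # input conditions differ from design labels
        conditions = sorted(by_condition)

    # --- QC ----------------------------------------------------------------
    reports: dict[str, CorrelationReport] = {}
    qc_summary = {}
    for cond in conditions:
        rep = replicate_correlations(by_condition[cond], layout)
        reports[cond] = rep
        qc_summary[cond] = {
            "mean_technical_r": rep.mean_technical_r,
            "mean_biological_r": rep.mean_biological_r,
            "pass": qc_gate(rep, config.qc_threshold),
        }
        with open(outdir / f"qc_{_safe(cond)}.tsv", "w", encoding="utf-8") as fh:
            keys = ["b%d_t%d" % k for k in rep.reaction_keys]
            fh.write("reaction\t" + "\t".join(keys) + "\n")
            for key, row in zip(keys, rep.pairwise):
                fh.write(key + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    qc_passed = all(s["pass"] for s in qc_summary.values())
    with open(outdir / "qc_summary.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"threshold": config.qc_threshold, "conditions": qc_summary, "pass": qc_passed},
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    if not qc_passed and not config.override_qc:
        manifest = _write_manifest(config, outdir, input_paths, qc_only=True)
        raise QCGateFailure(
            "replicate QC below threshold "
            f"{config.qc_threshold}; see {outdir / 'qc_summary.json'}"
        )

    # --- calling and scoring ----------------------------------------------
    profiles = {}
    for cond in conditions:
        calls = []
        for q in sorted(by_condition[cond], key=lambda q: q.key):
            cs = call_reaction(
                q,
                layout,
                threshold=config.call_threshold,
                method=config.call_method,
                zscore_k=config.zscore_k,
            )
            write_calls(outdir / f"calls_{_safe(cond)}_b{q.bio_rep}_t{q.tech_rep}.tsv", cs)
            calls.append(cs)
        profile = markov_scores(calls, layout, design=config.design)
        write_profile(outdir / f"profile_{_safe(cond)}.tsv", profile)
        profiles[cond] = profile
        summary = category_fractions(profile, layout, tau=config.tau)
        summary.to_frame().to_csv(
            outdir / f"categories_{_safe(cond)}.tsv", sep="\t", index=False
        )

    # --- differential comparison -------------------------------------------
    cond_a, cond_b = conditions
    diff = differential_categories(
        profiles[cond_a],
        profiles[cond_b],
        layout,
        tau=config.tau,
        n_perm=config.n_perm,
        seed=stage_seed(config.seed, _STAGE_PERMUTATION),
    )
    diff.table.to_csv(outdir / "differential.tsv", sep="\t", index=False)

    # Grey-scale matrix: category x condition phosphorylated fractions.
    grey = diff.table[["category"]].copy()
    grey[cond_a] = diff.table["f_A"]
    grey[cond_b] = diff.table["f_B"]
    grey.to_csv(outdir / "greyscale_matrix.tsv", sep="\t", index=False)

    manifest = _write_manifest(config, outdir, input_paths, qc_only=False)
    return RunResult(
        outdir=outdir,
        qc_reports=reports,
        qc_passed=qc_passed,
        differential=diff,
        manifest_path=manifest,
    )


def _safe(label: str) -> str:
    return "".join(c if (c.isalnum() or c in "-_") else "-" for c in label)


def _write_manifest(
    config: RunConfig, outdir: Path, input_paths: list[Path], qc_only: bool
) -> Path:
    outputs = sorted(
        p
        for p in outdir.glob("*.tsv")
        if p.is_file()
    ) + sorted(outdir.glob("*.json"))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_payload(config),
        "qc_only": qc_only,
        "inputs": {p.name: _sha256(p) for p in input_paths},
        "outputs": {p.name: _sha256(p) for p in outputs if p.name != "manifest.json"},
    }
    path = outdir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# config files


def _generation_config_from_dict(d: dict) -> GenerationConfig:
    d = dict(d)
    if "design" in d:
        dd = dict(d["design"])
        if "conditions" in dd:
            dd["conditions"] = tuple(dd["conditions"])
        d["design"] = StudyDesign(**dd)
    if "activity_multipliers" in d:
        flat = {}
        for cond, per_cat in d["activity_multipliers"].items():
            for cat, m in per_cat.items():
                flat[(cond, cat)] = float(m)
        d["activity_multipliers"] = flat
    return GenerationConfig(**d)


def load_run_config(path: str | os.PathLike, **overrides) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON file.

    The ``simulate`` section, if present, holds ``GenerationConfig``
    fields with ``activity_multipliers`` as a nested
    ``{condition: {category: multiplier}}`` mapping. Keyword overrides
    (e.g. from command-line flags) win over file values.
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "simulate" in data and data["simulate"] is not None:
        data["simulate"] = _generation_config_from_dict(data["simulate"])
    if "design" in data and data["design"] is not None and not isinstance(
        data["design"], StudyDesign
    ):
        dd = dict(data["design"])
        if "conditions" in dd:
            dd["conditions"] = tuple(dd["conditions"])
        data["design"] = StudyDesign(**dd)
    return RunConfig(**data)
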