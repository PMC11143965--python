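"""End-to-end orchestration: simulate -> mixture null -> DE -> validation.

One seeded root `SeedSequence` drives every stage through fixed substreams,
so a rerun with the same configuration and seed reproduces every artifact
byte for byte. Each stage's outputs land under the run directory together
with a provenance record (tool version, config hash, seed, timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import SecretomePanel
from .de import run_de
from .downstream import hierarchical_cluster, pca, preservation_score, vst
from .errors import CocomixError, ConfigError
from .io import write_composition, write_counts, write_panel
from .mixnull import build_virtual_cohort
from .secretome import analyte_report, build_virtual_secretome
from .synthdata import SimulationConfig, simulate_coculture_experiment, simulate_secretome

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    virtual_mode: str = "expected"  # or "sampled"
    virtual_total: int | None = None  # default: mean real-coculture depth
    alpha: float = 0.05
    min_count: int = 5
    max_fail_samples: int = 2
    paired: bool = True
    run_secretome: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        try:
            return cls(simulation=sim, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _provenance(config: PipelineConfig, stage: str, t0: float) -> dict:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return {
        "tool": "cocomix",
        "version": __version__,
        "stage": stage,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "started_unix": t0,
        "finished_unix": time.time(),
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every enabled stage, persisting artifacts and provenance.

    Returns the run directory. A stage failure raises with the failing stage
    named and leaves a ``FAILED`` marker file next to any partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=int(config.seed))
    stage = "simulate"
    try:
        t0 = time.time()
        matrix, compositions, truth = simulate_coculture_experiment(sim)
        write_counts(matrix, out / "counts.tsv")
        write_composition(compositions, out / "composition.csv")
        (out / "ground_truth.json").write_text(json.dumps({
            "interaction_genes": truth.interaction_genes,
            "log2fc": {g: float(v) for g, v in truth.log2fc.items() if v != 0.0},
        }, indent=1))
        _dump(out, "simulate", _provenance(config, stage, t0))

        stage = "mixnull"
        t0 = time.time()
        singles = matrix.subset_samples(
            matrix.samples_with_role("sc_single") + matrix.samples_with_role("fb_single")
        )
        real = matrix.subset_samples(matrix.samples_with_role("real"))
        total = config.virtual_total or int(real.counts.sum(axis=0).mean())
        virtual = build_virtual_cohort(
            singles, compositions, total=total, mode=config.virtual_mode, seed=config.seed
        )
        cohort = real.concat(virtual)
        write_counts(cohort, out / "cohort_counts.tsv")
        _dump(out, "mixnull", _provenance(config, stage, t0))

        stage = "interaction_de"
        t0 = time.time()
        de_table, signature, fit = run_de(
            cohort, alpha=config.alpha, min_count=config.min_count,
            max_fail_samples=config.max_fail_samples, paired=config.paired,
        )
        de_table.to_csv(out / "de_results.tsv", sep="\t", index_label="gene_id")
        sig_table = de_table.loc[signature.genes]
        sig_table.to_csv(out / "signature.tsv", sep="\t", index_label="gene_id")
        (out / "signature.json").write_text(json.dumps({
            "alpha": signature.alpha,
            "up": signature.up_genes,
            "down": signature.down_genes,
        }, indent=1))
        _dump(out, "interaction_de", _provenance(config, stage, t0))

        stage = "downstream"
        t0 = time.time()
        expr = vst(cohort)
        scores, _, varexp = pca(expr, n_components=2)
        scores.assign(variance_explained_pc1=varexp[0]).to_csv(out / "pca_scores.csv")
        results = {"n_signature_genes": len(signature.genes)}
        if signature.genes:
            sig_expr = expr.loc[[g for g in signature.genes if g in expr.index]]
            keep = sig_expr.std(axis=1) > 0
            if keep.sum() >= 2:
                tree = hierarchical_cluster(sig_expr.loc[keep])
                (out / "cluster_tree.nwk").write_text(tree.to_newick() + "\n")
                preservation = preservation_score(signature, cohort, "real", "virtual")
                results["preservation_score"] = preservation.score
                results["groups_separate"] = bool(preservation.groups_separate)
        (out / "downstream.json").write_text(json.dumps(results, indent=1))
        _dump(out, "downstream", _provenance(config, stage, t0))

        if config.run_secretome:
            stage = "secretome"
            t0 = time.time()
            panel, secretome_truth = simulate_secretome(sim)
            single_ids = panel.samples_with_role("sc_single") + panel.samples_with_role("fb_single")
            singles_panel = SecretomePanel(
                panel.values[single_ids], panel.samples.loc[single_ids]
            )
            comp = secretome_truth.compositions
            virt_panel = build_virtual_secretome(singles_panel, comp)
            real_ids = panel.samples_with_role("real")
            full = SecretomePanel(
                panel.values[real_ids].join(virt_panel.values),
                pd.concat([panel.samples.loc[real_ids], virt_panel.samples]),
            )
            report = analyte_report(full)
            write_panel(panel, out / "secretome_panel.csv")
            report.to_csv(out / "secretome_report.csv")
            _dump(out, "secretome", _provenance(config, stage, t0))
    except CocomixError:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        raise CocomixError(f"pipeline failed in stage {stage!r}") from None
    return out


def _dump(out: Path, stage: str, record: dict) -> None:
    prov_dir = out / "provenance"
    prov_dir.mkdir(exist_ok=True)
    (prov_dir / f"{stage}.json").write_text(json.dumps(record, indent=1))
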