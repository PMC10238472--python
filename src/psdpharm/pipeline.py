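"""Pipeline driver: simulate -> normalize -> rollup -> differential ->
network enrichment -> drug nomination -> reversal evaluation, with a JSON
manifest (parameters, seed, per-output SHA-256 hashes) for exact re-runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, network, pharmacology, qc, reversal, rollup, tsv
from .containers import GROUP_ADNP, GROUP_ADP
from .simulate import (
    SimulationConfig,
    generate_cohort,
    generate_peptide_data,
    generate_pharmacology_fixtures,
    generate_treatment_experiment,
)

STAGES = [
    "simulate",
    "normalize",
    "rollup",
    "differential",
    "enrich",
    "nominate",
    "evaluate_reversal",
]
STAGE_DEPS = {
    "normalize": ["simulate"],
    "rollup": ["normalize"],
    "differential": ["rollup"],
    "enrich": ["differential"],
    "nominate": ["differential"],
    "evaluate_reversal": ["differential"],
}


@dataclass
class PipelineConfig:
    """Stage toggles, parameters and output location for one run."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulation: dict = field(default_factory=dict)
    present_call: float = 1.0
    outlier_k: float = 3.0
    pecora_alpha: float = 0.01
    covariates: list[str] = field(
        default_factory=lambda: ["age", "pmi", "sex", "apoe4", "lewy_body", "log2_ptau"]
    )
    de_alpha: float = 0.05
    min_shared: int = 10
    corr_alpha: float = 0.01
    reversal_fraction: float = 0.6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        enabled = set(self.stages)
        for stage in self.stages:
            missing = set(STAGE_DEPS.get(stage, [])) - enabled
            if missing:
                raise ValueError(
                    f"stage {stage!r} requires disabled stage(s) {sorted(missing)}"
                )
        if not 0.0 < self.present_call <= 1.0:
            raise ValueError("present_call must be in (0, 1]")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages and write artifacts plus a manifest.

    Returns the manifest dict. Raises on the first stage failure; outputs
    written before the failure are renamed with a ``.partial`` suffix.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    artifacts: dict[str, object] = {}
    sim = SimulationConfig(**{"rng_seed": config.seed, **config.simulation})

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    try:
        if "simulate" in config.stages:
            cohort = generate_cohort(sim)
            matrix, truth = generate_peptide_data(sim, cohort)
            artifacts["cohort"] = cohort
            artifacts["matrix"] = matrix
            artifacts["truth"] = truth
            tsv.write_sample_meta(cohort, emit(out_dir / "cohort.tsv"))
            for p in tsv.write_peptide_matrix(matrix, out_dir / "peptides"):
                emit(p)
            tsv.write_json(
                {
                    "altered_set": truth.altered_set,
                    "uncorrelated_peptides": truth.uncorrelated_peptides,
                    "true_effect_per_protein": truth.true_effect_per_protein.to_dict(),
                },
                emit(out_dir / "ground_truth.json"),
            )

        if "normalize" in config.stages:
            normalized, report = qc.normalize_pipeline(
                artifacts["matrix"],
                present_call=config.present_call,
                outlier_k=config.outlier_k,
            )
            artifacts["normalized"] = normalized
            tsv.write_json(report.to_dict(), emit(out_dir / "normalization_report.json"))

        if "rollup" in config.stages:
            adjusted = rollup.yield_adjust(artifacts["normalized"], artifacts["cohort"])
            flags = rollup.pecora_flag(
                adjusted, artifacts["cohort"], alpha=config.pecora_alpha
            )
            pm = rollup.rollup_protein(adjusted, flags)
            artifacts["protein_matrix"] = pm
            tsv.write_protein_matrix(pm, emit(out_dir / "proteins.tsv"))
            tsv.write_table(flags.table, emit(out_dir / "pecora_flags.tsv"), index=False)

        if "differential" in config.stages:
            spec = differential.ContrastSpec(
                name="ADP_vs_ADNP",
                group_a=GROUP_ADP,
                group_b=GROUP_ADNP,
                covariates=config.covariates,
            )
            result = differential.fit_contrast(
                artifacts["protein_matrix"], artifacts["cohort"], spec
            )
            artifacts["differential"] = result
            t, df, p = differential.global_shift_test(result)
            artifacts["global_shift"] = {"t": t, "df": df, "p": p}
            tsv.write_table(result, emit(out_dir / "differential.tsv"))
            tsv.write_json(artifacts["global_shift"], emit(out_dir / "global_shift.json"))
            full_sig = pharmacology.build_signature(result, mode="full")
            top_sig = pharmacology.build_signature(
                result, mode="top", alpha=config.de_alpha
            )
            artifacts["full_sig"] = full_sig
            artifacts["top_sig"] = top_sig
            tsv.write_signature(full_sig, emit(out_dir / "signature_full.tsv"))
            tsv.write_signature(top_sig, emit(out_dir / "signature_top.tsv"))

        if "enrich" in config.stages:
            result = artifacts["differential"]
            rng = np.random.default_rng([config.seed, 10])
            proteins = list(result.index)
            de = differential.de_set(result, alpha=config.de_alpha)
            seed_set = list(rng.choice(proteins, size=min(23, len(proteins)), replace=False))
            # synthetic edge list biased toward DE proteins so the demo
            # enrichment is non-trivial
            others = [p for p in proteins if p not in seed_set]
            edges = []
            for s in seed_set:
                partners = rng.choice(others, size=min(6, len(others)), replace=False)
                for q in partners:
                    bias = 0.5 if q in de else 0.15
                    if rng.random() < bias:
                        edges.append((s, q, float(rng.uniform(0.4, 1.0))))
            graph = network.InteractionGraph(
                pd.DataFrame(edges, columns=["protein_a", "protein_b", "score"])
            )
            enr = network.interaction_enrichment(graph, seed_set, de, proteins)
            artifacts["enrichment"] = enr
            tsv.write_edge_list(graph, emit(out_dir / "edges.tsv"))
            tsv.write_json(
                {k: v for k, v in enr.items() if k != "table"}
                | {"table": enr["table"].tolist()},
                emit(out_dir / "enrichment.json"),
            )

        if "nominate" in config.stages:
            atlas, drugs, lincs = generate_pharmacology_fixtures(
                sim,
                artifacts["truth"],
                artifacts["full_sig"],
                top_entities=artifacts["top_sig"].entities,
            )
            nom = pharmacology.run_pharmacology(
                atlas,
                drugs,
                lincs,
                artifacts["full_sig"],
                artifacts["top_sig"],
                min_shared=config.min_shared,
                corr_alpha=config.corr_alpha,
            )
            artifacts["nominations"] = nom
            tsv.write_atlas(atlas, emit(out_dir / "knockdown_atlas.tsv"))
            tsv.write_table(drugs, emit(out_dir / "drug_targets.tsv"), index=False)
            tsv.write_table(lincs, emit(out_dir / "lincs_profiles.tsv"), index=False)
            tsv.write_table(nom.table, emit(out_dir / "nominations.tsv"), index=False)

        if "evaluate_reversal" in config.stages:
            mouse, mouse_meta = generate_treatment_experiment(
                sim,
                artifacts["full_sig"],
                reversal_fraction=config.reversal_fraction,
            )
            mm = qc.zeros_to_missing(mouse)
            flags = None
            pm = rollup.rollup_protein(mm, flags)
            labels = mouse_meta["arm"]
            fc = reversal.treatment_log2fc(pm, labels)
            res = reversal.reversal_test(
                fc, artifacts["full_sig"], artifacts["top_sig"]
            )
            artifacts["reversal"] = res
            tsv.write_table(fc.to_frame(), emit(out_dir / "treatment_log2fc.tsv"))
            tsv.write_json(res.summary(), emit(out_dir / "reversal_summary.json"))
    except Exception:
        for p in written:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in written},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
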