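"""End-to-end orchestration: simulate -> diff -> motifs -> rbp -> celltypes -> clinical.

Stages communicate through files (TSV/GMT/FASTA), so any stage can be
re-run independently; a machine-readable manifest records stage statuses,
output paths with checksums, and the full parameter echo, which is enough
to reproduce a run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import clinical as clin
from . import differential as da
from . import io_formats as iof
from . import motifs as mo
from . import rbp as rb
from . import synthetic_data as synth
from . import targets as tg

logger = logging.getLogger(__name__)

STAGES = ("simulate", "diff", "motifs", "rbp", "celltypes", "clinical")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    workdir: str = "sevmir_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # simulation
    n_mirnas: int = 500
    motif: str = "GCGC"
    carrier_fraction: float = 0.2
    secretion_shift_log2: float = 2.0
    dispersion: float = 0.1
    replicates: int = 3
    n_patients: int = 300
    hazard_coefficient: float = 1.0
    # thresholds
    profile: str = "screen"
    p_adj_threshold: float = 0.05
    min_motif_set_size: int = 6
    k_min: int = 4
    k_max: int = 7
    n_perm: int = 1000
    cluster_k: int = 4
    cutpoint_grid: str = "all"
    cutpoint_permutations: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.profile not in da.PROFILES:
            raise ValueError(f"unknown classification profile {self.profile!r}")
        if not 0 < self.p_adj_threshold < 1:
            raise ValueError("p_adj_threshold must be in (0, 1)")
        if self.min_motif_set_size < 1 or self.k_min < 1 or self.k_min > self.k_max:
            raise ValueError("invalid motif screen thresholds")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def simulation_config(self) -> synth.SimulationConfig:
        return synth.SimulationConfig(
            seed=self.seed,
            n_mirnas=self.n_mirnas,
            motif=self.motif,
            carrier_fraction=self.carrier_fraction,
            secretion_shift_log2=self.secretion_shift_log2,
            dispersion=self.dispersion,
            replicates=self.replicates,
            cohort=synth.CohortConfig(
                n_patients=self.n_patients,
                hazard_coefficient=self.hazard_coefficient,
            ),
        )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


# ---------------------------------------------------------------------------
# Stage implementations (file in, file out)
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, inputs: Path) -> list[Path]:
    inputs.mkdir(parents=True, exist_ok=True)
    sim_cfg = cfg.simulation_config()
    seqs, counts, rbp_table, mrna_table, markers, clinical, truth = synth.simulate_bundle(
        sim_cfg
    )
    paths = {
        "fasta": inputs / "mature.fasta",
        "counts": inputs / "counts.tsv",
        "samples": inputs / "samples.tsv",
        "rbp": inputs / "mirna_rbp.tsv",
        "mrna": inputs / "mirna_mrna.tsv",
        "markers": inputs / "markers.tsv",
        "clinical": inputs / "clinical.tsv",
        "truth": inputs / "truth.json",
    }
    iof.write_sequences_fasta(seqs, paths["fasta"])
    iof.write_count_matrix(counts, paths["counts"], paths["samples"])
    iof.write_interaction_table(rbp_table, paths["rbp"])
    iof.write_interaction_table(mrna_table, paths["mrna"])
    iof.write_marker_table(markers, paths["markers"])
    iof.write_clinical_table(clinical, paths["clinical"])
    paths["truth"].write_text(
        json.dumps(
            {
                "carrier_ids": truth.carrier_ids,
                "true_log2fc": truth.true_log2fc,
                "enriched_rbp_ids": truth.enriched_rbp_ids,
                "true_cell_type": truth.true_cell_type,
                "patient_scores": truth.patient_scores,
            },
            indent=1,
        )
    )
    logger.info(
        "simulate: %d miRNAs (%d carriers), %d samples, %d patients",
        len(seqs), len(truth.carrier_ids), len(counts.sample_ids),
        len(clinical.patient_ids),
    )
    return list(paths.values())


def read_differential_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table["tested"] = table["tested"].astype(bool)
    return table


def stage_diff(cfg: RunConfig, inputs: Path, outputs: Path) -> list[Path]:
    outputs.mkdir(parents=True, exist_ok=True)
    counts = iof.read_count_matrix(inputs / "counts.tsv", inputs / "samples.tsv")
    table = da.differential_test(counts)
    table = da.classify_compartments(table, profile=cfg.profile)
    n_sec = int((table["compartment"] == "secretory").sum())
    n_ret = int((table["compartment"] == "retained").sum())
    logger.info(
        "diff: %d/%d miRNAs tested; %d secretory, %d retained (%s profile)",
        int(table["tested"].sum()), len(table), n_sec, n_ret, cfg.profile,
    )
    diff_path = outputs / "differential.tsv"
    table.to_csv(diff_path, sep="\t", index_label="mirna_id")
    clusters = da.cluster_expression(counts, k=cfg.cluster_k)
    cluster_path = outputs / "clusters.tsv"
    clusters.to_csv(cluster_path, sep="\t", index_label="mirna_id")
    return [diff_path, cluster_path]


def stage_motifs(cfg: RunConfig, inputs: Path, outputs: Path) -> list[Path]:
    outputs.mkdir(parents=True, exist_ok=True)
    table = read_differential_table(outputs / "differential.tsv")
    seqs = iof.read_sequences_fasta(inputs / "mature.fasta")
    screen_cfg = mo.MotifScreenConfig(
        k_min=cfg.k_min,
        k_max=cfg.k_max,
        min_size=cfg.min_motif_set_size,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
    )
    result = mo.motif_screen(table, seqs, screen_cfg)
    logger.info(
        "motifs: %d surviving sets; %d at joint FDR < %.2f",
        len(result), int((result["fdr_joint"] < cfg.p_adj_threshold).sum()),
        cfg.p_adj_threshold,
    )
    result_path = outputs / "motif_enrichment.tsv"
    result.to_csv(result_path, sep="\t", index_label="motif")
    sets = mo.build_motif_sets(
        list(result.index), seqs, min_size=cfg.min_motif_set_size
    )
    gmt_path = outputs / "motif_sets.gmt"
    iof.write_gmt({k: set(v) for k, v in sets.items()}, gmt_path)

    # running-sum profiles for the top sorting and retention motifs
    ranked = da.ranked_list(table)
    ranked = ranked.loc[[m for m in ranked.index if m in seqs]]
    profile_rows = {}
    for motif in list(result.index[:3]) + list(result.index[-3:]):
        score = mo.enrichment_score(ranked, sets[motif])
        profile_rows[motif] = score.running
    profiles = pd.DataFrame(profile_rows, index=ranked.index)
    profile_path = outputs / "motif_running_profiles.tsv"
    profiles.to_csv(profile_path, sep="\t", index_label="mirna_id")
    return [result_path, gmt_path, profile_path]


def stage_rbp(cfg: RunConfig, inputs: Path, outputs: Path) -> list[Path]:
    outputs.mkdir(parents=True, exist_ok=True)
    table = read_differential_table(outputs / "differential.tsv")
    interactions = iof.read_interaction_table(inputs / "mirna_rbp.tsv", kind="mirna-rbp")
    universe = set(table.index[table["tested"]])
    written = []
    for compartment in ("secretory", "retained"):
        enriched = set(table.index[table["compartment"] == compartment])
        if not enriched:
            logger.info("rbp: no %s miRNAs; screen skipped", compartment)
            continue
        contingencies = rb.build_contingencies(interactions, enriched, universe)
        result = rb.rbp_screen(
            contingencies, rb.RbpScreenConfig(p_adj_threshold=cfg.p_adj_threshold)
        )
        logger.info(
            "rbp[%s]: %d RBPs tested, %d significant",
            compartment, len(result),
            int((result["p_adjusted"] < cfg.p_adj_threshold).sum()),
        )
        full = outputs / f"rbp_enrichment_{compartment}.tsv"
        result.to_csv(full, sep="\t", index_label="rbp_id")
        top = outputs / f"rbp_top10_{compartment}.tsv"
        result[result["top"].fillna(False)].to_csv(top, sep="\t", index_label="rbp_id")
        written.extend([full, top])
    return written


def stage_celltypes(cfg: RunConfig, inputs: Path, outputs: Path) -> list[Path]:
    outputs.mkdir(parents=True, exist_ok=True)
    table = read_differential_table(outputs / "differential.tsv")
    interactions = iof.read_interaction_table(inputs / "mirna_mrna.tsv", kind="mirna-mrna")
    markers = iof.read_marker_table(inputs / "markers.tsv")
    result = tg.cell_type_screen(
        table, interactions, markers, p_adj_threshold=cfg.p_adj_threshold
    )
    logger.info("celltypes: headline cell type %s", result.headline)
    enrichment_path = outputs / "celltype_enrichment.tsv"
    result.enrichment.to_csv(enrichment_path, sep="\t", index_label="cell_type")
    written = [enrichment_path]
    for cell_type, edges in result.subnetworks.items():
        safe = cell_type.replace("/", "_").replace(" ", "_")
        path = outputs / f"subnetwork_{safe}.sif"
        iof.write_sif(edges, path)
        written.append(path)
    return written


def stage_clinical(cfg: RunConfig, inputs: Path, outputs: Path) -> list[Path]:
    outputs.mkdir(parents=True, exist_ok=True)
    table = read_differential_table(outputs / "differential.tsv")
    clinical_table = iof.read_clinical_table(inputs / "clinical.tsv")
    signature = [
        m
        for m in table.index[table["compartment"] == "secretory"]
        if m in clinical_table.data.columns
    ]
    if not signature:
        raise ValueError("no secretory signature miRNA is quantified in the cohort")
    scores = clin.signature_score(clinical_table, signature)
    scores_path = outputs / "signature_scores.tsv"
    scores.to_csv(scores_path, sep="\t", index_label="patient_id")

    comparisons = clin.occult_contrast(scores["score"], clinical_table)
    pn_groups = clinical_table.data["pN"]
    try:
        anova = clin.compare_groups(scores["score"], pn_groups, design="multi_group")
        comparisons["pN_stages_anova"] = {
            "status": "ok", "statistic": anova.statistic, "p": anova.p,
            "group_sizes": anova.group_sizes,
        }
    except ValueError as exc:
        comparisons["pN_stages_anova"] = {"status": "skipped", "reason": str(exc)}
    comp_path = outputs / "clinical_comparisons.tsv"
    pd.DataFrame(comparisons).T.to_csv(comp_path, sep="\t", index_label="contrast")

    cut = clin.optimal_cutpoint_survival(
        scores["score"],
        clinical_table.data["time"],
        clinical_table.data["event"],
        grid_policy=cfg.cutpoint_grid,
        n_permutations=cfg.cutpoint_permutations,
        seed=cfg.seed,
    )
    logger.info(
        "clinical: cutpoint %.3f, log-rank p %.3g, high arm worse: %s",
        cut.cutpoint, cut.p, cut.high_arm_worse,
    )
    scan_path = outputs / "cutpoint_scan.tsv"
    cut.scan.to_csv(scan_path, sep="\t", index=False)
    written = [scores_path, comp_path, scan_path]
    for label, curve in cut.fit.curves.items():
        path = outputs / f"km_{label}.tsv"
        curve.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

_REQUIRED_INPUTS = {
    "diff": ["counts.tsv", "samples.tsv"],
    "motifs": ["mature.fasta"],
    "rbp": ["mirna_rbp.tsv"],
    "celltypes": ["mirna_mrna.tsv", "markers.tsv"],
    "clinical": ["clinical.tsv"],
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages in dependency order and write a manifest.

    Pre-flight checks verify that every enabled stage's inputs will exist
    before anything runs; a stage failure halts downstream stages and is
    recorded in the manifest.
    """
    workdir = Path(cfg.workdir)
    inputs = workdir / "inputs"
    outputs = workdir / "results"
    enabled = [s for s in STAGES if s in cfg.stages]

    simulate_on = "simulate" in enabled
    for stage in enabled:
        for fname in _REQUIRED_INPUTS.get(stage, []):
            if not simulate_on and not (inputs / fname).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} requires {inputs / fname}, which does not "
                    "exist and the simulate stage is disabled"
                )

    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "stages": {},
        "outputs": {},
    }
    runners = {
        "simulate": lambda: stage_simulate(cfg, inputs),
        "diff": lambda: stage_diff(cfg, inputs, outputs),
        "motifs": lambda: stage_motifs(cfg, inputs, outputs),
        "rbp": lambda: stage_rbp(cfg, inputs, outputs),
        "celltypes": lambda: stage_celltypes(cfg, inputs, outputs),
        "clinical": lambda: stage_clinical(cfg, inputs, outputs),
    }
    halted = False
    for stage in enabled:
        if halted:
            manifest["stages"][stage] = {"status": "not_run"}
            continue
        try:
            written = runners[stage]()
        except Exception as exc:  # recorded, downstream halted
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            halted = True
            continue
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": [str(p) for p in written],
        }
        for p in written:
            manifest["outputs"][str(p)] = _sha256(Path(p))
    workdir.mkdir(parents=True, exist_ok=True)
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
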