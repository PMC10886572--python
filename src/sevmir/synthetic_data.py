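"""Synthetic inputs with the statistical structure the analysis assumes.

Generates mature miRNA sequences with a planted sorting motif, negative-
binomial count experiments (two cell lines x {cell, sEV} x replicates) in
which motif carriers have elevated sEV:cell abundance, miRNA-RBP and
miRNA-mRNA interaction tables with biased binding to secretory miRNAs,
cell-type marker tables overlapping the secretory target pool, and a
clinical cohort whose nodal stage and hazard increase with a latent
signature score.  Every generator is deterministic given the seed, and the
planted ground truth is returned alongside each object so downstream
screens can be validated with known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    ClinicalTable,
    CountMatrix,
    InteractionTable,
    MarkerTable,
    SequenceSet,
)

RNA_BASES = np.array(list("ACGU"))


@dataclass
class RbpConfig:
    """Parameters of the simulated miRNA-RBP interaction layer."""

    n_rbps: int = 50
    enriched_rbp_count: int = 5
    p_bind_secretory: float = 0.5
    p_bind_background: float = 0.1


@dataclass
class MarkerConfig:
    """Parameters of the simulated target-gene / cell-type-marker layer."""

    n_cell_types: int = 9
    markers_per_type: int = 50
    target_overlap_fraction: float | None = 0.6  # None -> true type drawn like decoys
    n_genes: int = 20000
    targets_per_mirna: int = 40


@dataclass
class CohortConfig:
    """Parameters of the simulated clinical cohort."""

    n_patients: int = 300
    hazard_coefficient: float = 1.0  # gamma: log-hazard per unit latent score
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censoring_window: float = 3000.0  # uniform censoring horizon, days
    stage_logit_slope: float = 1.0
    cn_false_negative_rate: float = 0.3  # pN+ recorded cN0 -> occult cases
    expression_noise_sd: float = 0.5


@dataclass
class SimulationConfig:
    """Full configuration of the synthetic miRNA-secretome study.

    Defaults mirror the emulated study design: two cell lines, two
    compartments (cell, sEV), three biological replicates per group,
    a planted 4-mer sorting motif carried by 20% of miRNAs whose carriers
    gain a mean +2 log2 units of abundance in sEVs.
    """

    seed: int = 0
    n_mirnas: int = 500
    length_range: tuple[int, int] = (18, 25)
    motif: str = "GCGC"
    carrier_fraction: float = 0.2
    secretion_shift_log2: float = 2.0
    effect_sd: float = 0.25  # per-miRNA jitter of the log2 effect
    baseline_mean_log: float = float(np.log(100.0))
    baseline_mean_sdlog: float = 1.0
    dispersion: float = 0.1
    replicates: int = 3
    cell_lines: tuple[str, ...] = ("CAL27", "SCC25")
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    rbp: RbpConfig = field(default_factory=RbpConfig)
    marker: MarkerConfig = field(default_factory=MarkerConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if not 0 < self.carrier_fraction < 1:
            raise ValueError("carrier_fraction must be in (0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if set(self.motif) - set("ACGU"):
            raise ValueError("motif must be over {A, C, G, U}")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be (min, max) with min <= max")
        if len(self.motif) > self.length_range[0]:
            raise ValueError("motif longer than the minimum sequence length")
        for p in (self.rbp.p_bind_secretory, self.rbp.p_bind_background):
            if not 0 < p < 1:
                raise ValueError("binding probabilities must be in (0, 1)")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted truth recorded by the generators."""

    carrier_ids: list[str] = field(default_factory=list)
    true_log2fc: dict[str, float] = field(default_factory=dict)
    enriched_rbp_ids: list[str] = field(default_factory=list)
    true_cell_type: str | None = None
    patient_scores: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA_BASES, size=length))


def generate_sequences_with_motif(
    cfg: SimulationConfig, max_retries: int = 200
) -> tuple[SequenceSet, GroundTruth]:
    """Generate mature miRNA sequences with a planted motif in the carriers.

    Exactly ``round(carrier_fraction * n_mirnas)`` sequences contain the
    motif as a substring (inserted at a uniformly chosen position over an
    otherwise iid-uniform background); non-carriers are rejection-sampled
    to not contain it.

    Raises
    ------
    RuntimeError
        If rejection sampling cannot produce a motif-free sequence within
        ``max_retries`` draws (motif too short or too frequent to exclude).
    """
    rng = cfg.rng(stream=1)
    n_carriers = round(cfg.carrier_fraction * cfg.n_mirnas)
    lo, hi = cfg.length_range
    width = len(str(cfg.n_mirnas))
    ids = [f"mir-{i + 1:0{width}d}" for i in range(cfg.n_mirnas)]
    carrier_idx = set(rng.choice(cfg.n_mirnas, size=n_carriers, replace=False))

    sequences: dict[str, str] = {}
    carriers: list[str] = []
    for i, mirna_id in enumerate(ids):
        length = int(rng.integers(lo, hi + 1))
        if i in carrier_idx:
            # insert the motif into a random background at a uniform offset
            for _ in range(max_retries):
                background = _random_sequence(rng, length - len(cfg.motif))
                pos = int(rng.integers(0, len(background) + 1))
                seq = background[:pos] + cfg.motif + background[pos:]
                if cfg.motif in seq:
                    break
            sequences[mirna_id] = seq
            carriers.append(mirna_id)
        else:
            for attempt in range(max_retries):
                seq = _random_sequence(rng, length)
                if cfg.motif not in seq:
                    break
            else:
                raise RuntimeError(
                    f"could not sample a sequence free of {cfg.motif!r} in "
                    f"{max_retries} tries; use a longer or rarer motif"
                )
            sequences[mirna_id] = seq
    truth = GroundTruth(carrier_ids=carriers)
    return SequenceSet(sequences), truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def simulate_count_experiment(
    cfg: SimulationConfig, carriers: list[str] | None = None, mirna_ids=None
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the count experiment: NB counts with planted sEV enrichment.

    Count of miRNA g in sample j is NB with mean
    ``s_j * lambda_g * 2**(beta_g * [j is sEV])`` and dispersion ``alpha``
    (variance mu + alpha * mu**2).  ``beta_g`` is Normal(shift, effect_sd)
    for carriers and Normal(0, effect_sd) otherwise; ``s_j`` is log-uniform
    on ``size_factor_range``.  The realized beta of every miRNA is recorded
    in the returned truth.
    """
    rng = cfg.rng(stream=2)
    if mirna_ids is None:
        width = len(str(cfg.n_mirnas))
        mirna_ids = [f"mir-{i + 1:0{width}d}" for i in range(cfg.n_mirnas)]
    mirna_ids = list(mirna_ids)
    carriers = list(carriers or [])
    unknown = set(carriers) - set(mirna_ids)
    if unknown:
        raise ValueError(f"carriers not among simulated miRNAs: {sorted(unknown)[:3]}")
    n = len(mirna_ids)
    is_carrier = np.array([m in set(carriers) for m in mirna_ids])

    sample_ids, conditions, lines = [], [], []
    for line in cfg.cell_lines:
        for condition in ("cell", "sev"):
            for rep in range(1, cfg.replicates + 1):
                sample_ids.append(f"{line}_{condition}_{rep}")
                conditions.append(condition)
                lines.append(line)
    is_sev = np.array([c == "sev" for c in conditions])

    lam = rng.lognormal(cfg.baseline_mean_log, cfg.baseline_mean_sdlog, size=n)
    beta = rng.normal(0.0, cfg.effect_sd, size=n)
    beta[is_carrier] += cfg.secretion_shift_log2
    log_lo, log_hi = np.log(cfg.size_factor_range)
    s = np.exp(rng.uniform(log_lo, log_hi, size=len(sample_ids)))

    mu = s[None, :] * lam[:, None] * np.power(2.0, beta[:, None] * is_sev[None, :])
    if cfg.dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / cfg.dispersion
        # NB as a gamma-Poisson mixture: mean mu, variance mu + alpha*mu^2
        counts = rng.poisson(rng.gamma(shape, mu / shape))

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=mirna_ids, columns=sample_ids),
        sample_meta=pd.DataFrame(
            {"condition": conditions, "cell_line": lines}, index=sample_ids
        ),
    )
    truth = GroundTruth(
        carrier_ids=carriers,
        true_log2fc=dict(zip(mirna_ids, beta.tolist())),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# Interactions and markers
# ---------------------------------------------------------------------------


def simulate_interaction_tables(
    cfg: SimulationConfig, truth: GroundTruth, mirna_ids=None
) -> tuple[InteractionTable, InteractionTable, MarkerTable]:
    """Simulate miRNA-RBP and miRNA-mRNA edges plus cell-type markers.

    Enriched RBPs bind secretory (carrier) miRNAs with ``p_bind_secretory``
    and all other pairs occur at ``p_bind_background``.  Every miRNA targets
    a random gene subset; the designated true cell type's markers overlap
    the pooled carrier target set at ``target_overlap_fraction`` while decoy
    types draw their markers uniformly from the gene universe (the
    hypergeometric chance level).
    """
    rng = cfg.rng(stream=3)
    if mirna_ids is None:
        width = len(str(cfg.n_mirnas))
        mirna_ids = [f"mir-{i + 1:0{width}d}" for i in range(cfg.n_mirnas)]
    mirna_ids = list(mirna_ids)
    carriers = set(truth.carrier_ids)
    is_secretory = np.array([m in carriers for m in mirna_ids])

    rcfg = cfg.rbp
    rbp_ids = [f"RBP{i + 1:03d}" for i in range(rcfg.n_rbps)]
    enriched = rbp_ids[: rcfg.enriched_rbp_count]
    p = np.full((len(rbp_ids), len(mirna_ids)), rcfg.p_bind_background)
    p[: rcfg.enriched_rbp_count, is_secretory] = rcfg.p_bind_secretory
    bound = rng.random(p.shape) < p
    rbp_rows = [
        (mirna_ids[j], rbp_ids[i]) for i, j in zip(*np.nonzero(bound))
    ]
    rbp_table = InteractionTable(
        edges=pd.DataFrame(rbp_rows, columns=["source", "target"]), kind="mirna-rbp"
    )

    mcfg = cfg.marker
    genes = np.array([f"GENE{i + 1:05d}" for i in range(mcfg.n_genes)])
    mrna_rows = []
    target_sets: dict[str, np.ndarray] = {}
    for mirna in mirna_ids:
        chosen = rng.choice(mcfg.n_genes, size=mcfg.targets_per_mirna, replace=False)
        target_sets[mirna] = chosen
        mrna_rows.extend((mirna, genes[g]) for g in sorted(chosen))
    mrna_table = InteractionTable(
        edges=pd.DataFrame(mrna_rows, columns=["source", "target"]), kind="mirna-mrna"
    )

    pool_idx = np.unique(
        np.concatenate([target_sets[m] for m in mirna_ids if m in carriers])
        if carriers
        else np.array([], dtype=int)
    )
    non_pool_idx = np.setdiff1d(np.arange(mcfg.n_genes), pool_idx)

    markers: dict[str, frozenset[str]] = {}
    true_type = "celltype_true"
    for t in range(mcfg.n_cell_types):
        name = true_type if t == 0 else f"celltype_decoy{t:02d}"
        if t == 0 and mcfg.target_overlap_fraction is not None:
            k_in = round(mcfg.target_overlap_fraction * mcfg.markers_per_type)
            k_out = mcfg.markers_per_type - k_in
            chosen = np.concatenate(
                [
                    rng.choice(pool_idx, size=min(k_in, len(pool_idx)), replace=False),
                    rng.choice(non_pool_idx, size=k_out, replace=False),
                ]
            )
        else:
            chosen = rng.choice(mcfg.n_genes, size=mcfg.markers_per_type, replace=False)
        markers[name] = frozenset(genes[g] for g in chosen)

    truth.enriched_rbp_ids = enriched
    truth.true_cell_type = true_type
    return rbp_table, mrna_table, MarkerTable(markers)


# ---------------------------------------------------------------------------
# Clinical cohort
# ---------------------------------------------------------------------------

_PN_POSITIVE_PROBS = (0.5, 0.35, 0.15)  # N1 : N2 : N3 split among node-positive


def simulate_clinical_cohort(
    cfg: SimulationConfig, signature: list[str]
) -> tuple[ClinicalTable, GroundTruth]:
    """Simulate a cohort whose stage and hazard track a latent signature score.

    Each patient has a latent score z ~ N(0,1).  Signature miRNA expression
    is ``2**(10 + z + noise)`` so that log2 expression carries z plus noise;
    survival time is exponential with rate ``baseline_hazard * exp(gamma*z)``
    under independent uniform censoring; P(pN >= N1) = logistic(slope * z);
    cN equals pN except that node-positive patients are recorded cN0 with
    the configured false-negative rate, creating occult-metastasis cases.
    """
    if not signature:
        raise ValueError("signature must be non-empty")
    rng = cfg.rng(stream=4)
    ccfg = cfg.cohort
    n = ccfg.n_patients
    patient_ids = [f"patient_{i + 1:04d}" for i in range(n)]

    z = rng.normal(0.0, 1.0, size=n)
    expr = {}
    for mirna in signature:
        noise = rng.normal(0.0, ccfg.expression_noise_sd, size=n)
        expr[mirna] = np.power(2.0, 10.0 + z + noise)

    rate = ccfg.baseline_hazard * np.exp(ccfg.hazard_coefficient * z)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, ccfg.censoring_window, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 0.5)  # keep times strictly positive (days)

    p_positive = 1.0 / (1.0 + np.exp(-ccfg.stage_logit_slope * z))
    node_positive = rng.random(n) < p_positive
    pn = np.where(
        node_positive,
        rng.choice(["N1", "N2", "N3"], size=n, p=_PN_POSITIVE_PROBS),
        "N0",
    )
    occult_mask = node_positive & (rng.random(n) < ccfg.cn_false_negative_rate)
    cn = np.where(occult_mask, "N0", pn)
    pt = rng.choice(["T1", "T2", "T3", "T4"], size=n, p=[0.2, 0.35, 0.3, 0.15])

    data = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "pT": pt,
            "pN": pn,
            "cN": cn,
            **expr,
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )
    truth = GroundTruth(patient_scores=dict(zip(patient_ids, z.tolist())))
    return ClinicalTable(data=data, expression_columns=list(signature)), truth


# ---------------------------------------------------------------------------
# Full fixture bundle
# ---------------------------------------------------------------------------


def simulate_bundle(cfg: SimulationConfig):
    """Generate the full coherent fixture set for one seed.

    Returns ``(sequences, counts, rbp_table, mrna_table, markers, clinical,
    truth)`` with a single merged :class:`GroundTruth`.
    """
    seqs, truth = generate_sequences_with_motif(cfg)
    counts, count_truth = simulate_count_experiment(
        cfg, carriers=truth.carrier_ids, mirna_ids=seqs.ids()
    )
    truth.true_log2fc = count_truth.true_log2fc
    rbp_table, mrna_table, markers = simulate_interaction_tables(
        cfg, truth, mirna_ids=seqs.ids()
    )
    clinical, cohort_truth = simulate_clinical_cohort(cfg, truth.carrier_ids)
    truth.patient_scores = cohort_truth.patient_scores
    return seqs, counts, rbp_table, mrna_table, markers, clinical, truth
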