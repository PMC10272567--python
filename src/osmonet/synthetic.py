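"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates a 2 genotypes x 2 organs x 2 treatments x 3
replicates hydroponic design. Gene g's log2 intensity in sample s is

    baseline_g + sign_g * archetype_g(organ, treatment)
    + module_loading * L_g * u_{module(g), s} + eps_{g, s}

where the archetype term plants the eight treatment-response patterns, the
per-module latent factor u plants co-expression, L_g > 0 for members and is
amplified for hubs, and ``sign_g = -1`` for anti-hubs (their structured
signal is negated, so their first-neighbor correlations are negative —
the fight-club mechanism). Intensities are exponentiated to the raw scale;
probes replicate their gene with small noise, and conflict probes carry the
negated treatment pattern so probe-level fold changes disagree in sign.

By default the latent factors are re-centered within each design cell so
they are orthogonal to all treatment contrasts: co-expression structure
then cannot confound mean-based stages (DE, condition means). Setting
``center_factors=False`` restores i.i.d. per-sample factors, under which
two same-module genes with loadings La, Lb have expected correlation

    La*Lb*m^2 / sqrt((La^2 m^2 + sd_a^2) (Lb^2 m^2 + sd_b^2)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, OsmonetError, ProbeGeneMap, SampleDesign, TFAnnotation

logger = logging.getLogger(__name__)

TF_FAMILIES = (
    "bHLH", "ERF", "MYB", "HD-ZIP", "NAC", "WRKY", "bZIP", "GATA", "C3H", "G2-like",
)


@dataclass(frozen=True)
class Archetype:
    """One planted expression pattern.

    ``leaf_effect`` / ``root_effect`` are PEG-vs-control shifts in log2
    units (identical in both genotypes); ``root_offset`` is a constitutive
    log2 offset of root over leaf baseline; ``weight`` is the fraction of
    genes drawn with this pattern.
    """

    name: str
    leaf_effect: float
    root_effect: float
    root_offset: float = 0.0
    weight: float = 0.125

    def effect(self, organ: str) -> float:
        return self.leaf_effect if organ == "leaf" else self.root_effect


#: the eight default response patterns: strong down/up in both organs, a
#: root-specific down/up pair, a root-strong-down pattern with minor leaf
#: response, a leaf-specific up pattern, an organ-contrasting pattern, and
#: an organ-offset slight-down pattern.
DEFAULT_ARCHETYPES: tuple[Archetype, ...] = (
    Archetype("root_down", 0.0, -2.0, 0.0, 0.14),
    Archetype("leaf_down_root_up", -2.0, 2.0, 0.0, 0.10),
    Archetype("root_up", 0.0, 2.0, 0.0, 0.14),
    Archetype("organ_diff_down", -1.7, -1.7, 3.0, 0.10),
    Archetype("leaf_up", 2.0, 0.5, 0.0, 0.12),
    Archetype("down_both", -2.0, -2.0, 0.0, 0.08),
    Archetype("root_strong_down", -0.5, -2.5, 1.5, 0.12),
    Archetype("up_both", 2.0, 2.0, 0.0, 0.20),
)


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 2000
    n_tf: int = 150
    archetypes: tuple[Archetype, ...] = DEFAULT_ARCHETYPES
    module_loading: float = 0.15
    n_hubs_per_module: int = 2
    n_anti_hubs: int = 3
    anti_hub_module: str = "up_both"
    noise_sd: float = 0.25
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 1.5
    probes_per_gene: tuple[float, float, float] = (0.6, 0.3, 0.1)  # P(1), P(2), P(3)
    conflict_fraction: float = 0.02
    seed: int = 0
    # secondary knobs
    hub_loading: float = 1.2
    hub_noise_factor: float = 0.3
    member_noise_jitter: tuple[float, float] = (1.35, 1.8)
    probe_noise_sd: float = 0.05
    decoy_fraction: float = 0.15
    low_identity_fraction: float = 0.05
    conflict_min_effect: float = 1.5
    center_factors: bool = True
    genotypes: tuple[str, str] = ("M82", "Tondo")
    n_replicates: int = 3

    def validate(self) -> None:
        problems = []
        if self.n_genes < len(self.archetypes):
            problems.append("n_genes smaller than number of archetypes")
        if not 0 <= self.conflict_fraction < 1:
            problems.append("conflict_fraction must be in [0, 1)")
        if self.n_tf > self.n_genes:
            problems.append("n_tf exceeds n_genes")
        if not 0 < self.module_loading <= 1.5:
            problems.append("module_loading out of range")
        if abs(sum(self.probes_per_gene) - 1.0) > 1e-9:
            problems.append("probes_per_gene weights must sum to 1")
        if self.anti_hub_module not in {a.name for a in self.archetypes}:
            problems.append(f"anti_hub_module {self.anti_hub_module!r} not an archetype")
        if problems:
            raise OsmonetError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class SimTruth:
    """Planted ground truth: one row per gene and one row per probe."""

    genes: pd.DataFrame  # index gene_id: archetype, module, is_hub, is_anti_hub, is_tf, leaf_effect, root_effect
    probes: pd.DataFrame  # index probe_id: gene_id, is_conflict

    def de_status(self, organ: str, lfc_min: float = 1.0) -> pd.Series:
        """Planted DE sign per gene for PEG-vs-control in ``organ``.

        +1 / -1 when the planted |effect| reaches ``lfc_min`` (anti-hub sign
        folded in), else 0.
        """
        eff = self.genes[f"{organ}_effect"] * np.where(self.genes["is_anti_hub"], -1, 1)
        return pd.Series(
            np.where(eff >= lfc_min, 1, np.where(eff <= -lfc_min, -1, 0)),
            index=self.genes.index,
        )


def _build_design(cfg: SimConfig) -> SampleDesign:
    rows = []
    for organ in ("leaf", "root"):
        for genotype in cfg.genotypes:
            for treatment in ("control", "peg"):
                for rep in range(1, cfg.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{organ}_{genotype}_{treatment}_{rep}",
                            "genotype": genotype,
                            "organ": organ,
                            "treatment": treatment,
                            "replicate": rep,
                        }
                    )
    return SampleDesign(pd.DataFrame(rows).set_index("sample_id"))


def _archetype_counts(cfg: SimConfig) -> list[int]:
    weights = np.array([a.weight for a in cfg.archetypes], dtype=float)
    weights = weights / weights.sum()
    counts = np.floor(weights * cfg.n_genes).astype(int)
    counts = np.maximum(counts, 1)
    # distribute the remainder by largest fractional part
    while counts.sum() < cfg.n_genes:
        frac = weights * cfg.n_genes - counts
        counts[int(np.argmax(frac))] += 1
    while counts.sum() > cfg.n_genes:
        counts[int(np.argmax(counts))] -= 1
    return counts.tolist()


def generate(
    cfg: SimConfig = SimConfig(),
) -> tuple[ExpressionMatrix, SampleDesign, ProbeGeneMap, TFAnnotation, SimTruth]:
    """Generate a probe-level raw matrix plus design, probe map, TF labels
    and planted truth. Fully reproducible given ``cfg.seed`` (PCG64
    generator)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    design = _build_design(cfg)
    samples = design.sample_ids
    n_samples = len(samples)
    organ_of = design.table["organ"].to_dict()
    treat_of = design.table["treatment"].to_dict()

    counts = _archetype_counts(cfg)
    gene_ids = [f"Gene{i + 1:06d}" for i in range(cfg.n_genes)]
    archetype_idx = np.repeat(np.arange(len(cfg.archetypes)), counts)

    genes = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    genes["archetype"] = [cfg.archetypes[i].name for i in archetype_idx]
    genes["module"] = archetype_idx + 1
    genes["leaf_effect"] = [cfg.archetypes[i].leaf_effect for i in archetype_idx]
    genes["root_effect"] = [cfg.archetypes[i].root_effect for i in archetype_idx]
    root_offset = np.array([cfg.archetypes[i].root_offset for i in archetype_idx])

    # hubs: first n_hubs_per_module genes of each module; anti-hubs: extra
    # genes of the designated module with negated structured signal
    is_hub = np.zeros(cfg.n_genes, dtype=bool)
    is_anti = np.zeros(cfg.n_genes, dtype=bool)
    for mod in range(len(cfg.archetypes)):
        members = np.flatnonzero(archetype_idx == mod)
        is_hub[members[: cfg.n_hubs_per_module]] = True
    anti_mod = next(i for i, a in enumerate(cfg.archetypes) if a.name == cfg.anti_hub_module)
    anti_pool = np.flatnonzero((archetype_idx == anti_mod) & ~is_hub)
    if cfg.n_anti_hubs > len(anti_pool):
        raise OsmonetError("n_anti_hubs exceeds available genes in anti_hub_module")
    is_anti[anti_pool[: cfg.n_anti_hubs]] = True
    genes["is_hub"] = is_hub
    genes["is_anti_hub"] = is_anti

    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    loading = np.where(is_hub, cfg.hub_loading, 1.0)
    loading = np.where(is_anti, -1.0, loading)
    sign = np.where(is_anti, -1.0, 1.0)
    lo, hi = cfg.member_noise_jitter
    noise_scale = rng.uniform(lo, hi, cfg.n_genes)
    noise_scale[is_hub | is_anti] = cfg.hub_noise_factor
    gene_sd = cfg.noise_sd * noise_scale
    genes["loading"] = loading
    genes["noise_sd"] = gene_sd

    # per-module per-sample latent factors
    u = rng.standard_normal((len(cfg.archetypes), n_samples))
    if cfg.center_factors:
        cell_key = [f"{organ_of[s]}|{design.table.loc[s, 'genotype']}|{treat_of[s]}" for s in samples]
        for key in set(cell_key):
            mask = np.array([k == key for k in cell_key])
            u[:, mask] -= u[:, mask].mean(axis=1, keepdims=True)

    effect = np.zeros((cfg.n_genes, n_samples))
    offset = np.zeros((cfg.n_genes, n_samples))
    for j, s in enumerate(samples):
        organ = organ_of[s]
        if treat_of[s] == "peg":
            col = "leaf_effect" if organ == "leaf" else "root_effect"
            effect[:, j] = genes[col].to_numpy()
        if organ == "root":
            offset[:, j] = root_offset

    log2_vals = (
        baseline[:, None]
        + offset
        + sign[:, None] * effect
        + cfg.module_loading * loading[:, None] * u[archetype_idx, :]
        + rng.normal(0.0, 1.0, (cfg.n_genes, n_samples)) * gene_sd[:, None]
    )

    gene_matrix = pd.DataFrame(np.power(2.0, log2_vals), index=gene_ids, columns=samples)

    # ----- probes ---------------------------------------------------------
    n_probes_per = rng.choice([1, 2, 3], size=cfg.n_genes, p=list(cfg.probes_per_gene))
    eligible = (
        (np.maximum(np.abs(genes["leaf_effect"]), np.abs(genes["root_effect"])) >= cfg.conflict_min_effect)
        & ~is_anti
    ).to_numpy()
    n_conflict = int(round(cfg.conflict_fraction * cfg.n_genes))
    conflict_genes = rng.choice(np.flatnonzero(eligible), size=min(n_conflict, int(eligible.sum())), replace=False)
    conflict_set = set(conflict_genes.tolist())
    n_probes_per[list(conflict_set)] = np.maximum(n_probes_per[list(conflict_set)], 2)

    probe_rows = []
    probe_values = []
    probe_counter = 0
    for gi, gid in enumerate(gene_ids):
        base_log2 = log2_vals[gi]
        neg_log2 = base_log2 - 2.0 * sign[gi] * effect[gi]  # treatment pattern negated
        for k in range(n_probes_per[gi]):
            probe_counter += 1
            pid = f"TC{probe_counter:06d}"
            is_conflict = gi in conflict_set and k == n_probes_per[gi] - 1
            src = neg_log2 if is_conflict else base_log2
            vals = src + rng.normal(0.0, cfg.probe_noise_sd, n_samples)
            probe_rows.append((pid, gid, is_conflict))
            probe_values.append(np.power(2.0, vals))

    probes = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id", "is_conflict"]).set_index("probe_id")
    matrix = ExpressionMatrix(
        pd.DataFrame(np.vstack(probe_values), index=probes.index.copy(), columns=samples),
        scale_tag="raw",
    )

    # ----- probe->gene map (BLAST-tabular style, with decoys) -------------
    map_rows = []
    for pid, row in probes.iterrows():
        identity = float(rng.uniform(92.0, 100.0))
        score = float(rng.uniform(180.0, 240.0))
        map_rows.append((pid, row["gene_id"], round(identity, 2), round(score, 1)))
        if rng.random() < cfg.decoy_fraction:
            decoy = gene_ids[int(rng.integers(cfg.n_genes))]
            if decoy != row["gene_id"]:
                map_rows.append(
                    (pid, decoy, round(float(rng.uniform(90.0, 99.0)), 2),
                     round(score - float(rng.uniform(5.0, 50.0)), 1))
                )
        if rng.random() < cfg.low_identity_fraction:
            decoy = gene_ids[int(rng.integers(cfg.n_genes))]
            map_rows.append(
                (pid, decoy, round(float(rng.uniform(70.0, 89.9)), 2),
                 round(float(rng.uniform(100.0, 170.0)), 1))
            )
    probe_map = ProbeGeneMap(
        pd.DataFrame(map_rows, columns=["probe_id", "gene_id", "identity_pct", "score"])
    )

    # ----- TF labels ------------------------------------------------------
    forced = np.flatnonzero(is_hub | is_anti)
    others = np.flatnonzero(~(is_hub | is_anti))
    n_extra = max(0, cfg.n_tf - forced.size)
    extra = rng.choice(others, size=min(n_extra, others.size), replace=False)
    tf_idx = np.sort(np.concatenate([forced, extra]))
    tf_table = pd.DataFrame(
        {
            "gene_id": [gene_ids[i] for i in tf_idx],
            "tf_family": rng.choice(TF_FAMILIES, size=tf_idx.size),
        }
    )
    genes["is_tf"] = genes.index.isin(tf_table["gene_id"])

    truth = SimTruth(genes=genes, probes=probes)
    logger.info(
        "generated %d genes / %d probes / %d TFs (%d hubs, %d anti-hubs, %d conflict genes)",
        cfg.n_genes, len(probes), tf_idx.size, int(is_hub.sum()), int(is_anti.sum()), len(conflict_set),
    )
    return matrix, design, probe_map, TFAnnotation(tf_table), truth


def gene_level_matrix(cfg: SimConfig = SimConfig()) -> tuple[ExpressionMatrix, SampleDesign, TFAnnotation, SimTruth]:
    """Convenience: generate and return the clean gene-level matrix (no
    probe redundancy), for tests of downstream stages."""
    matrix, design, probe_map, tf, truth = generate(cfg)
    clean = truth.probes[~truth.probes["is_conflict"]]
    first = clean.reset_index().drop_duplicates("gene_id", keep="first")
    vals = matrix.values.loc[first["probe_id"]].copy()
    vals.index = first["gene_id"].tolist()
    vals = vals.sort_index()
    return ExpressionMatrix(vals, scale_tag="raw"), design, tf, truth


# ---------------------------------------------------------------------------
# physiology tables
# ---------------------------------------------------------------------------

DEFAULT_PHYSIO_MEANS = {
    # (genotype, treatment) -> (RWC mean, EL mean)
    ("M82", "control"): (88.0, 12.0),
    ("M82", "peg"): (47.5, 46.7),
    ("Tondo", "control"): (88.0, 12.0),
    ("Tondo", "peg"): (55.0, 42.2),
}


def generate_physio(
    means: dict[tuple[str, str], tuple[float, float]] | None = None,
    sd: float = 3.0,
    n_replicates: int = 7,
    seed: int = 0,
) -> pd.DataFrame:
    """Physiology replicate table per genotype x treatment.

    Draws ``n_replicates`` RWC and EL percentages per group from
    Normal(mean, sd), truncated to [0, 100]. Deterministic given ``seed``.
    """
    means = DEFAULT_PHYSIO_MEANS if means is None else means
    rng = np.random.default_rng(seed)
    rows = []
    for (genotype, treatment), (rwc_mu, el_mu) in means.items():
        rwc_vals = np.clip(rng.normal(rwc_mu, sd, n_replicates), 0.0, 100.0)
        el_vals = np.clip(rng.normal(el_mu, sd, n_replicates), 0.0, 100.0)
        for rep in range(n_replicates):
            rows.append(
                {
                    "genotype": genotype,
                    "treatment": treatment,
                    "replicate": rep + 1,
                    "rwc_pct": rwc_vals[rep],
                    "el_pct": el_vals[rep],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DE-table fixture encoding for count bookkeeping
# ---------------------------------------------------------------------------


def encode_det_counts(
    spec: dict[str, dict[str, tuple[int, int] | int]],
    genotypes: tuple[str, str] = ("M82", "Tondo"),
) -> pd.DataFrame:
    """Build a DE results table realizing given per-organ DET counts.

    ``spec`` maps organ -> {"common": n or (n_up, n_down),
    "<genotype>": (n_up, n_down), ...}. Common genes are DETs in both
    genotypes with the same direction; specific genes are DETs in exactly
    one genotype. The returned frame has the columns
    :func:`osmonet.pipeline.report_counts` consumes.
    """
    rows = []
    for organ, counts in spec.items():
        common = counts.get("common", 0)
        if isinstance(common, int):
            common = (common, 0)
        gi = 0
        for direction, n in zip(("up", "down"), common):
            for _ in range(n):
                gi += 1
                gene = f"{organ}_common_{gi:06d}"
                for g in genotypes:
                    rows.append((gene, organ, g, True, direction))
        for g in genotypes:
            if g not in counts:
                continue
            n_up, n_down = counts[g]
            for direction, n in zip(("up", "down"), (n_up, n_down)):
                for i in range(n):
                    gene = f"{organ}_{g}_{direction}_{i:06d}"
                    rows.append((gene, organ, g, True, direction))
    return pd.DataFrame(
        rows, columns=["gene_id", "organ", "genotype", "is_det", "direction"]
    )
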