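"""End-to-end orchestration: simulate -> process -> assign -> metrics ->
validate, plus the filtering/truncation settings sweep.

The default :class:`RunConfig` encodes the synthetic validation design: a
mock community spanning 8 arthropod orders (one of them a parasite order)
with Dirichlet(1) biomass, 20 camera sessions of 150 deliveries scored at
order-level precision 0.9, and one fecal sample per session sequenced at
10,000 read pairs with 0.5% per-base error, 2% chimeras and 5% host reads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import amplicon, metrics, stats, synthetic, taxonomy
from .amplicon import MergedRead, Otu, OtuTable, PipelineSettings
from .synthetic import PARASITE_ORDERS, MockCommunity, SimulationConfig

#: Target arthropod classes retained after pruning (matches the classes a
#: nest-camera can record, plus Chilopoda).
ARTHROPOD_CLASSES = frozenset(
    {"Arachnida", "Insecta", "Chilopoda", "Diplopoda", "Malacostraca"}
)


@dataclass
class RunConfig:
    """Configuration for a full synthetic validation run."""

    seed: int = 0
    out_dir: str | None = None
    # community
    n_orders: int = 8
    n_parasite_orders: int = 1
    families_per_order: int = 2
    genera_per_family: int = 2
    n_taxa: int = 12
    concentration: float = 1.0
    amplification_sd: float = 0.3
    # cameras
    n_sessions: int = 20
    items_per_session: int = 150
    rank_precision: dict = field(default_factory=lambda: {"order": 0.9})
    size_noise_sd: float = 0.3
    # sequencing
    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            read_depth_per_sample=10_000,
            per_base_error_rate=0.005,
            chimera_rate=0.02,
            host_read_fraction=0.05,
            control_contamination_reads=70,
            sample_contamination_reads=5,
        )
    )
    settings: PipelineSettings = field(default_factory=PipelineSettings)
    ranks: tuple[str, ...] = ("order", "family")
    parasite_orders: frozenset = PARASITE_ORDERS

    def validate(self) -> None:
        if self.n_taxa < 1 or self.n_sessions < 1:
            raise ValueError("n_taxa and n_sessions must be >= 1")
        # nested dataclasses validate themselves in __post_init__


def _child_seed(master: int, stage: int, index: int = 0) -> int:
    """Deterministic per-stage child seed derived from the master seed."""
    return int(
        np.random.SeedSequence([master, stage, index]).generate_state(1)[0]
        % (2**31)
    )


def simulate_study(config: RunConfig) -> dict:
    """Generate library, community, camera sessions and per-sample reads."""
    config.validate()
    library, taxonomy_table = synthetic.generate_reference_library(
        n_orders=config.n_orders,
        families_per_order=config.families_per_order,
        genera_per_family=config.genera_per_family,
        seed=_child_seed(config.seed, 1),
        n_parasite_orders=config.n_parasite_orders,
    )
    community = synthetic.generate_mock_diet(
        library,
        config.n_taxa,
        config.concentration,
        seed=_child_seed(config.seed, 2),
        amplification_sd=config.amplification_sd,
        require_parasite=config.n_parasite_orders > 0,
    )
    sessions = []
    for i in range(config.n_sessions):
        sessions.extend(
            synthetic.simulate_camera_session(
                community,
                config.items_per_session,
                rank_precision_probs=config.rank_precision,
                size_noise_sd=config.size_noise_sd,
                seed=_child_seed(config.seed, 3, i),
                session_id=f"CAM{i + 1:02d}",
            )
        )
    samples = []
    for i in range(config.n_sessions):
        sim_cfg = replace(
            config.simulation,
            seed=_child_seed(config.seed, 4, i),
            control_contamination_reads=(
                config.simulation.control_contamination_reads if i == 0 else 0
            ),
        )
        samples.append(
            synthetic.simulate_reads(community, sim_cfg, sample_id=f"S{i + 1:02d}")
        )
    return {
        "library": library,
        "taxonomy_table": taxonomy_table,
        "community": community,
        "camera_items": sessions,
        "samples": samples,
    }


def process_study(study: dict, settings: PipelineSettings) -> dict:
    """Merge/truncate/filter every sample, cluster pooled OTUs, map reads and
    subtract the pooled negative controls."""
    per_sample_trunc: dict[str, list[MergedRead]] = {}
    pooled_filtered: list[MergedRead] = []
    control_trunc: list[MergedRead] = []
    log = {}
    for sim in study["samples"]:
        merged = amplicon.merge_pairs(
            sim.pairs, settings.min_overlap, settings.max_overlap_diff_rate
        )
        trunc = amplicon.truncate(merged, settings.primer_trunc, settings.trunc_len)
        retained, rejected = amplicon.filter_expected_errors(trunc, settings.max_ee)
        per_sample_trunc[sim.sample_id] = trunc
        pooled_filtered.extend(retained)
        log[sim.sample_id] = {
            "input_pairs": len(sim.pairs),
            "merged": len(merged),
            "truncated": len(trunc),
            "ee_retained": len(retained),
            "ee_rejected": len(rejected),
        }
        if sim.control_pairs:
            cm = amplicon.merge_pairs(
                sim.control_pairs, settings.min_overlap, settings.max_overlap_diff_rate
            )
            control_trunc.extend(
                amplicon.truncate(cm, settings.primer_trunc, settings.trunc_len)
            )
    uniques = amplicon.dereplicate(pooled_filtered, settings.remove_singletons)
    otus = amplicon.cluster_otus(uniques, settings.otu_identity)
    table, unassigned = amplicon.map_reads_to_otus(
        per_sample_trunc, otus, settings.map_identity
    )
    control_counts = (
        amplicon.control_counts_from_table(control_trunc, otus, settings.map_identity)
        if control_trunc
        else {}
    )
    adjusted = amplicon.subtract_negative_controls(table, control_counts)
    return {
        "otus": otus,
        "raw_table": table,
        "table": adjusted,
        "control_counts": control_counts,
        "unassigned": unassigned,
        "log": log,
    }


def _mean_profile(profiles: list[metrics.DietProfile]) -> pd.Series:
    """Two-step mean over units after dropping/renormalizing "unknown"."""
    named = [metrics.drop_unknown(p) for p in profiles]
    named = [p for p in named if p.proportions]
    if not named:
        return pd.Series(dtype=float)
    return metrics.aggregate_mean_rra(named)["mean"]


def validate_against_camera(
    table: OtuTable,
    assignments: pd.DataFrame,
    camera_items,
    ranks=("order", "family"),
    exclude=PARASITE_ORDERS,
) -> dict:
    """Mean per-taxon RRA vs mean per-taxon RSBC Pearson correlation at each
    rank, pairing named taxa only (union of taxa, absent = 0)."""
    out = {}
    for rank in ranks:
        rra = metrics.compute_rra(table, assignments, rank, exclude=exclude)
        rsbc = metrics.compute_rsbc(camera_items, rank, exclude=exclude)
        mean_rra = _mean_profile(rra)
        mean_rsbc = _mean_profile(rsbc)
        taxa = sorted(set(mean_rra.index) | set(mean_rsbc.index))
        x = [mean_rra.get(t, 0.0) for t in taxa]
        y = [mean_rsbc.get(t, 0.0) for t in taxa]
        if len(taxa) >= 3 and len(set(x)) > 1 and len(set(y)) > 1:
            res = stats.pearson_with_ci(x, y)
            out[rank] = {
                "r": res.r,
                "ci": (res.ci_low, res.ci_high),
                "p": res.p,
                "n_taxa": len(taxa),
                "mean_rra": mean_rra.to_dict(),
                "mean_rsbc": mean_rsbc.to_dict(),
            }
        else:
            out[rank] = {"r": float("nan"), "n_taxa": len(taxa)}
    return out


def truth_order_proportions(study: dict) -> pd.Series:
    """Realized efficiency-weighted per-order read proportions from the
    truth tables (taxon-category reads only, parasite orders excluded)."""
    truth = pd.concat([s.truth for s in study["samples"]])
    truth = truth[truth["category"] == "taxon"]
    acc_to_order = {
        m.ref.accession: m.ref.rank("order") for m in study["community"].members
    }
    orders = truth["source"].map(acc_to_order)
    counts = orders[~orders.isin(PARASITE_ORDERS)].value_counts()
    return counts / counts.sum()


def truth_order_proportions_by_sample(study: dict) -> pd.DataFrame:
    """Per-sample per-order truth read proportions (samples x orders)."""
    truth = pd.concat([s.truth for s in study["samples"]])
    truth = truth[truth["category"] == "taxon"].copy()
    acc_to_order = {
        m.ref.accession: m.ref.rank("order") for m in study["community"].members
    }
    truth["order"] = truth["source"].map(acc_to_order)
    truth = truth[~truth["order"].isin(PARASITE_ORDERS)]
    counts = truth.groupby(["sample", "order"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def run_pipeline(config: RunConfig) -> dict:
    """Full run.  Returns a machine-readable summary; when ``config.out_dir``
    is set, all stage outputs plus the serialized config are written there."""
    study = simulate_study(config)
    processed = process_study(study, config.settings)
    search_library = study["library"] + [study["community"].host_ref]
    assignments = taxonomy.assign_taxonomy(processed["otus"], search_library)
    pruned, removed_fraction = taxonomy.prune_to_classes(
        processed["table"], assignments, ARTHROPOD_CLASSES
    )
    validation = validate_against_camera(
        pruned, assignments, study["camera_items"], ranks=config.ranks,
        exclude=config.parasite_orders,
    )

    # recovered vs true order proportions, sample by sample (truth oracle)
    truth_props = truth_order_proportions_by_sample(study)
    rra_order = metrics.compute_rra(
        pruned, assignments, "order", exclude=config.parasite_orders
    )
    rra_by_sample = {p.unit_id: metrics.drop_unknown(p).proportions
                     for p in rra_order}
    orders = sorted(
        set(truth_props.columns)
        | {t for p in rra_by_sample.values() for t in p}
    )
    xs, ys = [], []
    for sample, props in rra_by_sample.items():
        for o in orders:
            xs.append(props.get(o, 0.0))
            ys.append(
                float(truth_props.loc[sample, o])
                if sample in truth_props.index and o in truth_props.columns
                else 0.0
            )
    truth_vs_rra_r = float("nan")
    max_abs_diff = float("nan")
    if len(xs) >= 3 and len(set(xs)) > 1 and len(set(ys)) > 1:
        truth_vs_rra_r = stats.pearson_with_ci(xs, ys).r
        max_abs_diff = float(np.max(np.abs(np.array(xs) - np.array(ys))))

    total_unassigned = sum(processed["unassigned"].values())
    total_reads = sum(log["truncated"] for log in processed["log"].values())
    table_total = processed["table"].counts.values.sum()
    class_fractions = {}
    if table_total:
        per_class = {}
        for otu in processed["table"].otus:
            cls = assignments.loc[otu, "class"] or "unassigned"
            per_class[cls] = per_class.get(cls, 0) + int(
                processed["table"].counts.loc[otu].sum()
            )
        class_fractions = {c: v / table_total for c, v in per_class.items()}
    summary = {
        "seed": config.seed,
        "n_true_taxa": len(study["community"].members),
        "otu_count": len(processed["otus"]),
        "unassigned_reads": total_unassigned,
        "unassigned_fraction": (
            total_unassigned / total_reads if total_reads else 0.0
        ),
        "pruned_read_fraction": removed_fraction,
        "class_read_fractions": class_fractions,
        "control_counts": processed["control_counts"],
        "validation": validation,
        "truth_vs_rra_order_r": truth_vs_rra_r,
        "truth_vs_rra_max_abs_diff": max_abs_diff,
        "log": processed["log"],
    }

    if config.out_dir:
        _write_run(config, study, processed, assignments, summary)
    return {
        "study": study,
        "processed": processed,
        "assignments": assignments,
        "pruned_table": pruned,
        "summary": summary,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_run(config, study, processed, assignments, summary) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = asdict(config)
    cfg["parasite_orders"] = sorted(config.parasite_orders)
    (out / "config.json").write_text(json.dumps(_jsonable(cfg), indent=2, sort_keys=True))
    synthetic.write_fasta(study["library"], out / "reference.fasta")
    synthetic.write_taxonomy(study["taxonomy_table"], out / "reference_taxonomy.tsv")
    synthetic.write_camera_tsv(study["camera_items"], out / "camera_records.tsv")
    pd.concat([s.truth for s in study["samples"]]).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )
    with open(out / "otus.fasta", "w") as fh:
        for o in processed["otus"]:
            fh.write(f">{o.otu_id};size={o.size}\n{o.centroid}\n")
    processed["table"].counts.to_csv(out / "otu_table.tsv", sep="\t")
    assignments.to_csv(out / "assignments.tsv", sep="\t")
    # tidy long-format diet profiles and FOO at each configured rank
    profiles = []
    foo_rows = []
    for rank in config.ranks:
        profiles.extend(
            metrics.compute_rra(
                processed["table"], assignments, rank,
                exclude=config.parasite_orders,
            )
        )
        profiles.extend(
            metrics.compute_rsbc(
                study["camera_items"], rank, exclude=config.parasite_orders
            )
        )
        foo = metrics.compute_foo(
            metrics.table_unit_counts(processed["table"], assignments, rank)
        )
        foo_rows.extend((rank, t, n) for t, n in sorted(foo.items()))
    metrics.profiles_to_frame(profiles).to_csv(
        out / "profiles.tsv", sep="\t", index=False
    )
    pd.DataFrame(foo_rows, columns=["rank", "taxon", "foo"]).to_csv(
        out / "foo.tsv", sep="\t", index=False
    )
    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2, sort_keys=True)
    )


# ---------------------------------------------------------------------------
# Settings sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-variant per-taxon read counts plus the within-subject F statistic
    across variants (taxa as subjects)."""

    counts: pd.DataFrame  # variants x taxa
    diversity: pd.DataFrame  # richness / shannon per variant
    f_statistic: float


def within_subject_f(matrix: np.ndarray) -> float:
    """One-way repeated-measures F across rows (treatments) with columns as
    subjects: F = MS_treatment / MS_(treatment x subject)."""
    m = np.asarray(matrix, dtype=float)
    v, s = m.shape
    if v < 2 or s < 2:
        raise ValueError("need at least 2 variants and 2 subjects")
    grand = m.mean()
    ss_treat = s * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_subj = v * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = max(ss_total - ss_treat - ss_subj, 0.0)
    ms_treat = ss_treat / (v - 1)
    ms_err = ss_err / ((v - 1) * (s - 1))
    if ms_err == 0:
        return 0.0 if ms_treat == 0 else float("inf")
    return float(ms_treat / ms_err)


def sweep_settings(
    merged_reads: list[MergedRead],
    library,
    ee_values: list[float],
    trunc_values: list[int],
    settings: PipelineSettings = PipelineSettings(),
    rank: str = "order",
) -> SweepResult:
    """Re-run truncation + EE filtering + clustering per variant on the same
    merged reads and compare per-taxon read counts across variants.

    Variants are the EE values at the default truncation plus the truncation
    values at the default EE, mirroring a one-factor-at-a-time design."""
    if not ee_values and not trunc_values:
        raise ValueError("no sweep variants requested")
    variants = [("ee", ee, settings.trunc_len) for ee in ee_values] + [
        ("trunc", settings.max_ee, t) for t in trunc_values
    ]
    rows, div_rows, index = [], [], []
    for kind, ee, trunc_len in variants:
        vid = f"{kind}={ee if kind == 'ee' else trunc_len}"
        trunc = amplicon.truncate(merged_reads, settings.primer_trunc, trunc_len)
        retained, _ = amplicon.filter_expected_errors(trunc, ee)
        uniques = amplicon.dereplicate(retained, settings.remove_singletons)
        otus = amplicon.cluster_otus(uniques, settings.otu_identity)
        table, _ = amplicon.map_reads_to_otus(
            {"pooled": trunc}, otus, settings.map_identity
        )
        assignments = taxonomy.assign_taxonomy(otus, library)
        by_taxon = metrics.counts_by_taxon(table, assignments, rank).groupby(
            level="taxon"
        ).sum()["pooled"]
        rows.append(by_taxon)
        richness, shannon = metrics.alpha_diversity(by_taxon.to_dict())
        div_rows.append({"richness": richness, "shannon": shannon})
        index.append(vid)
    counts = pd.DataFrame(rows, index=index).fillna(0.0)
    diversity = pd.DataFrame(div_rows, index=index)
    f = within_subject_f(counts.values) if counts.shape[1] >= 2 else 0.0
    return SweepResult(counts=counts, diversity=diversity, f_statistic=f)
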