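"""End-to-end orchestration: simulate/load -> filter -> hybrid screen ->
ancestry -> phase -> place -> mito-mismatch -> clonal clusters -> diversity
-> egg typing, with per-stage report tables and confusion matrices against
the planted truth when available.

Two nuances the stages share:

* the heterozygosity panel uses the full filter set (quality masking, indel
  removal, MAF and missingness), while phasing and consensus reconstruction
  run on the quality-masked, indel-free panel WITHOUT the MAF/missingness
  filters, which would discard exactly the low-frequency within-lineage
  variants that distinguish clonal from wild-type fathers;
* reference panels are built without consulting the truth table: the
  maternal reference is the highest-mean-depth non-F1 queen of the maternal
  species, species panels come from non-F1 individuals' consensus sequences,
  and the clonal/wild split of the paternal species comes from single-linkage
  clustering of its males.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .variant_store import CohortMatrix, filter_sites
from .synthetic_colonies import (
    SimScenario,
    SimulatedCohort,
    simulate_scenario,
    expected_pairwise_distance,
    MATERNAL_SPECIES,
    PATERNAL_SPECIES,
)
from . import hybrid_screen as hs
from . import haplome_phasing as hp
from . import lineage_placement as lp
from . import diversity_stats as ds

logger = logging.getLogger("xenopop")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "summarize_fig1"]


@dataclass
class PipelineConfig:
    scenario: SimScenario = field(default_factory=SimScenario)
    out_dir: Path | None = None
    seed: int = 0
    min_quality: float = 10.0
    min_maf: float = 0.05
    min_called: float = 0.8
    min_depth: int = 3
    strict_phasing_mode: bool = False
    f1_min_separation: float = 5.0
    freq_floor: float = 1e-3
    n_bootstrap: int = 100
    min_margin: float = 0.0
    clonal_threshold: float | None = None  # default: 3x expected clonal distance
    diversity_bootstrap: int = 200

    def resolved_clonal_threshold(self) -> float:
        if self.clonal_threshold is not None:
            return self.clonal_threshold
        pi_s = self.scenario.pi_s_targets["structor_clonal"]
        ratio = self.scenario.pi_n_over_pi_s_targets["structor_clonal"]
        return 3.0 * expected_pairwise_distance(pi_s, ratio)


@dataclass
class RunReport:
    individuals: pd.DataFrame
    diversity: pd.DataFrame
    group_summary: pd.DataFrame
    confusion: dict[str, pd.DataFrame]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.individuals.to_csv(out / "individual_report.tsv", sep="\t", index=False)
        self.diversity.to_csv(out / "diversity_report.tsv", sep="\t", index=False)
        self.group_summary.to_csv(out / "group_summary.tsv", sep="\t", index=False)
        for name, cm in self.confusion.items():
            cm.to_csv(out / f"confusion_{name}.tsv", sep="\t")
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=False)


def _mean_depth(cohort: CohortMatrix, individual_id: str) -> float:
    return float(cohort.depth[:, cohort.column(individual_id)].mean())


def select_maternal_reference(
    cohort: CohortMatrix, f1_ids: set[str], species: str = MATERNAL_SPECIES
) -> str:
    """Highest-mean-depth non-hybrid queen of the maternal species."""
    candidates = [
        m.individual_id
        for m in cohort.individuals
        if m.caste == "queen" and m.nominal_species == species and m.individual_id not in f1_ids
    ]
    if not candidates:
        raise ValueError(f"no non-hybrid {species} queen available as maternal reference")
    return max(candidates, key=lambda i: _mean_depth(cohort, i))


def run_pipeline(config: PipelineConfig, sim: SimulatedCohort | None = None) -> RunReport:
    """Run the full analysis on a simulated cohort (deterministic given seed).

    ``sim`` short-circuits simulation when the caller already has one (the
    acceptance checks reuse a single simulated cohort across stages).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if sim is None:
        scenario = config.scenario
        sim = simulate_scenario(scenario)
    scenario = sim.scenario
    cohort = sim.cohort
    if cohort.n_individuals == 0:
        raise ValueError("no individuals")
    logger.info("cohort: %d individuals, %d sites", cohort.n_individuals, cohort.n_sites)

    # --- stage 1: heterozygosity panel and F1 screen -----------------------
    het_panel = filter_sites(
        cohort,
        min_quality=config.min_quality,
        drop_indels=True,
        min_maf=config.min_maf,
        min_called=config.min_called,
    )
    logger.info("het panel: %d sites", het_panel.n_sites)
    adults = [
        m.individual_id for m in cohort.individuals if m.caste in ("queen", "worker", "male")
    ]
    profiles = hs.het_profiles(het_panel, adults)
    calls = hs.classify_f1(profiles, min_separation=config.f1_min_separation)
    f1_ids = {c.individual_id for c in calls if c.is_f1}
    by_id_prof = {p.individual_id: p for p in profiles}
    by_id_call = {c.individual_id: c for c in calls}

    # --- stage 2: ancestry --------------------------------------------------
    meta = {m.individual_id: m for m in cohort.individuals}
    maternal_src = [
        i for i in adults
        if i not in f1_ids and meta[i].nominal_species == MATERNAL_SPECIES
    ]
    paternal_src = [
        i for i in adults
        if i not in f1_ids and meta[i].nominal_species == PATERNAL_SPECIES
    ]
    ancestry: dict[str, hs.AncestryEstimate] = {}
    if maternal_src and paternal_src and f1_ids:
        freqs = (
            hs.allele_frequencies(het_panel, maternal_src),
            hs.allele_frequencies(het_panel, paternal_src),
        )
        for iid in sorted(f1_ids):
            try:
                ancestry[iid] = hs.estimate_ancestry(
                    het_panel, iid, freqs, freq_floor=config.freq_floor
                )
            except ValueError as exc:  # logged, marked indeterminate
                logger.warning("ancestry failed for %s: %s", iid, exc)

    # --- stage 3: phasing panel, consensus panels, haplomes ----------------
    phase_panel = filter_sites(
        cohort, min_quality=config.min_quality, drop_indels=True, min_maf=0.0, min_called=0.0
    )
    backbone = sim.reference_backbone
    gene_lengths = {g: len(s) for g, s in backbone.items()}
    mat_ref = select_maternal_reference(phase_panel, f1_ids)
    logger.info("maternal reference: %s", mat_ref)

    def concat(gene_seqs: dict[str, str]) -> str:
        return lp.concatenate_genes(gene_seqs, gene_lengths)

    consensus: dict[str, str] = {}
    for iid in adults:
        if iid in f1_ids:
            continue
        consensus[iid] = concat(
            hp.consensus_sequence(phase_panel, iid, backbone, min_depth=config.min_depth)
        )

    ib_panel = {i: consensus[i] for i in maternal_src}
    st_all = {i: consensus[i] for i in paternal_src}

    # clonal vs wild split of the paternal species, from its males only
    st_males = {i: s for i, s in st_all.items() if meta[i].caste == "male"}
    clusters = lp.detect_clonal_cluster(st_males, config.resolved_clonal_threshold()) if len(
        st_males
    ) >= 2 else None
    clonal_ids: set[str] = set()
    if clusters is not None and clusters.clonal_like >= 0:
        clonal_ids = set(clusters.clusters[clusters.clonal_like])
    clonal_panel = {i: st_all[i] for i in clonal_ids}
    wild_panel = {i: s for i, s in st_all.items() if i not in clonal_ids}

    # species-level nuclear assignment + mito assignment for all adults
    mito = sim.mito_sequences
    mito_refs = {}
    if maternal_src:
        mito_refs[MATERNAL_SPECIES] = mito[maternal_src[0]]
    wild_for_mito = [i for i in wild_panel if meta[i].caste == "male"] or list(wild_panel)
    if wild_for_mito:
        mito_refs[PATERNAL_SPECIES] = mito[wild_for_mito[0]]

    species_panels = {MATERNAL_SPECIES: ib_panel, PATERNAL_SPECIES: st_all}
    nuclear_place: dict[str, lp.PlacementResult] = {}
    mito_place: dict[str, lp.PlacementResult] = {}
    mismatch: dict[str, lp.MismatchFlag] = {}
    for iid in adults:
        if iid in f1_ids:
            continue
        panels = {
            sp: {k: v for k, v in panel.items() if k != iid}
            for sp, panel in species_panels.items()
        }
        panels = {sp: p for sp, p in panels.items() if p}
        if len(panels) < 2 or len(mito_refs) < 2:
            continue
        nuc = lp.assign_by_nearest_panel(
            consensus[iid], panels, query_id=iid,
            n_bootstrap=config.n_bootstrap, min_margin=config.min_margin, rng=rng,
        )
        mit = lp.assign_mito(
            mito[iid], mito_refs, query_id=iid, n_bootstrap=config.n_bootstrap, rng=rng
        )
        nuclear_place[iid] = nuc
        mito_place[iid] = mit
        mismatch[iid] = lp.detect_mito_nuclear_mismatch(nuc, mit)

    # --- stage 4: phase F1 workers, place paternal haplomes -----------------
    lineage_panels = {
        "ibericus": ib_panel,
        "structor_clonal": clonal_panel,
        "structor_wild": wild_panel,
    }
    lineage_panels = {k: v for k, v in lineage_panels.items() if v}
    species_of = {
        "ibericus": MATERNAL_SPECIES,
        "structor_clonal": PATERNAL_SPECIES,
        "structor_wild": PATERNAL_SPECIES,
    }
    paternal_place: dict[str, lp.PlacementResult] = {}
    assigned_fraction: dict[str, float] = {}
    for iid in sorted(f1_ids):
        phased = hp.phase_individual(
            phase_panel, iid, mat_ref, min_depth=config.min_depth,
            strict=config.strict_phasing_mode, f1_ids=f1_ids,
        )
        _, pat = hp.build_haplome_sequences(phased, backbone, iid)
        assigned_fraction[iid] = pat.assigned_fraction
        if len(lineage_panels) >= 2:
            paternal_place[iid] = lp.assign_by_nearest_panel(
                concat(pat.gene_sequences), lineage_panels, query_id=iid,
                n_bootstrap=config.n_bootstrap, min_margin=config.min_margin, rng=rng,
            )
        if len(mito_refs) >= 2:
            mito_place[iid] = lp.assign_mito(
                mito[iid], mito_refs, query_id=iid, n_bootstrap=config.n_bootstrap, rng=rng
            )

    # --- stage 5: diversity per lineage (haploid males only: their
    # consensus is a full haplotype, so pairwise pi is unbiased) ------------
    genes_by_group = {}
    ib_males = [i for i in maternal_src if meta[i].caste == "male"]
    groups = {
        "ibericus": ib_males,
        "structor_clonal": sorted(clonal_ids),
        "structor_wild": sorted(i for i in wild_panel if meta[i].caste == "male"),
    }
    from .variant_store import GeneSequenceSet

    div_rows = []
    for label, ids in groups.items():
        if len(ids) < 2:
            continue
        per_gene = {}
        for iid in ids:
            cons = hp.consensus_sequence(phase_panel, iid, backbone, min_depth=config.min_depth)
            for g, s in cons.items():
                per_gene.setdefault(g, {})[iid] = s
        gsets = [
            GeneSequenceSet.from_sequences(g, seqs)
            for g, seqs in sorted(per_gene.items())
            if len(seqs) >= 2
        ]
        genes_by_group[label] = gsets
        est = ds.pi_with_ci(
            gsets, n_bootstrap=config.diversity_bootstrap, seed=rng
        )
        div_rows.append(
            {
                "lineage": label,
                "n_sequences": est.n_sequences,
                "n_genes": est.n_genes,
                "pi_s": est.pi_s,
                "pi_s_ci_low": est.pi_s_ci[0],
                "pi_s_ci_high": est.pi_s_ci[1],
                "pi_n": est.pi_n,
                "pi_n_ci_low": est.pi_n_ci[0],
                "pi_n_ci_high": est.pi_n_ci[1],
                "ratio": est.ratio,
                "ratio_ci_low": est.ratio_ci[0],
                "ratio_ci_high": est.ratio_ci[1],
            }
        )
    diversity_df = pd.DataFrame(div_rows)

    # --- stage 6: egg typing -------------------------------------------------
    egg_class: dict[str, str] = {}
    eggs = [m.individual_id for m in cohort.individuals if m.caste == "egg"]
    if eggs and maternal_src and paternal_src:
        diag = lp.diagnostic_sites(het_panel, maternal_src, paternal_src)
        for iid in eggs:
            egg_class[iid] = lp.classify_embryo(het_panel, iid, diag)

    # --- report --------------------------------------------------------------
    rows = []
    for m in cohort.individuals:
        iid = m.individual_id
        prof = by_id_prof.get(iid)
        call = by_id_call.get(iid)
        nuc = nuclear_place.get(iid)
        pat = paternal_place.get(iid)
        mit = mito_place.get(iid)
        mmf = mismatch.get(iid)
        father = pat.assigned_group if pat else ""
        rows.append(
            {
                "individual_id": iid,
                "caste": m.caste,
                "nominal_species": m.nominal_species,
                "ploidy": m.ploidy,
                "het_sites": prof.het_sites if prof else np.nan,
                "panel_size": prof.panel_size if prof else np.nan,
                "het_proportion": prof.het_proportion if prof else np.nan,
                "is_f1": bool(call.is_f1) if call else False,
                "q_maternal": ancestry[iid].q_maternal if iid in ancestry else np.nan,
                "nuclear_group": nuc.assigned_group if nuc else (
                    "F1" if iid in f1_ids else ""
                ),
                "mito_species": mit.assigned_group if mit else "",
                "mito_mismatch": bool(mmf.is_mismatch) if mmf else False,
                "father_lineage": {"structor_clonal": "clonal", "structor_wild": "wild"}.get(
                    father, ""
                ),
                "paternal_support": pat.support if pat else np.nan,
                "assigned_fraction": assigned_fraction.get(iid, np.nan),
                "egg_class": egg_class.get(iid, ""),
            }
        )
    individuals_df = pd.DataFrame(rows)
    assert len(individuals_df) == cohort.n_individuals

    group_summary = summarize_fig1(individuals_df)
    confusion = _confusion_tables(individuals_df, sim)

    manifest = {
        "xenopop_version": __version__,
        "seed": config.seed,
        "scenario_seed": scenario.seed,
        "n_individuals": cohort.n_individuals,
        "n_sites": cohort.n_sites,
        "het_panel_sites": het_panel.n_sites,
        "phase_panel_sites": phase_panel.n_sites,
        "maternal_reference": mat_ref,
        "clonal_threshold": float(config.resolved_clonal_threshold()),
        "strict_phasing_mode": config.strict_phasing_mode,
        "input_checksum": hashlib.sha256(cohort.alleles.tobytes()).hexdigest()[:16],
    }
    report = RunReport(individuals_df, diversity_df, group_summary, confusion, manifest)
    if config.out_dir is not None:
        report.write(config.out_dir)
    return report


def summarize_fig1(individuals: pd.DataFrame) -> pd.DataFrame:
    """Group mean heterozygosity (F1 vs non-hybrid), rank-sum p, ancestry means."""
    adults = individuals[individuals["caste"].isin(["queen", "worker", "male"])]
    adults = adults.dropna(subset=["het_proportion"])
    f1 = adults[adults["is_f1"]]
    rest = adults[~adults["is_f1"]]
    rows = []
    for name, grp in (("F1_hybrid", f1), ("non_hybrid", rest)):
        rows.append(
            {
                "group": name,
                "n": len(grp),
                "mean_het": grp["het_proportion"].mean() if len(grp) else np.nan,
                "mean_q_maternal": grp["q_maternal"].mean() if len(grp) else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if len(f1) >= 1 and len(rest) >= 1 and (len(f1) > 1 or len(rest) > 1):
        p = hs.compare_groups(f1["het_proportion"], rest["het_proportion"])
        out["ranksum_p"] = p
        out["het_ratio"] = (
            out.loc[0, "mean_het"] / out.loc[1, "mean_het"]
            if out.loc[1, "mean_het"] > 0
            else np.inf
        )
    else:
        import warnings as _w

        _w.warn("group sizes too small for the rank-sum test; skipped")
    return out


def _confusion_tables(individuals: pd.DataFrame, sim: SimulatedCohort) -> dict[str, pd.DataFrame]:
    truth = sim.truth.to_frame()
    merged = individuals.merge(truth, on="individual_id", suffixes=("", "_true"))
    adults = merged[merged["caste"].isin(["queen", "worker", "male"])]
    out = {}
    pred_class = np.where(adults["is_f1"], "F1", "non_hybrid")
    true_class = np.where(adults["true_class"] == "F1", "F1", "non_hybrid")
    out["f1"] = pd.crosstab(
        pd.Series(true_class, name="true"), pd.Series(pred_class, name="called")
    )
    workers = merged[(merged["true_class"] == "F1") & (merged["caste"] == "worker")]
    if len(workers) and workers["father_lineage"].ne("").any():
        out["father_lineage"] = pd.crosstab(
            workers["true_father_lineage"].rename("true"),
            workers["father_lineage"].rename("called"),
        )
    males = merged[merged["caste"] == "male"]
    if len(males) and males["mito_species"].ne("").any():
        truth_mm = males["true_mito_species"] != np.where(
            males["nominal_species"] == MATERNAL_SPECIES, MATERNAL_SPECIES, PATERNAL_SPECIES
        )
        out["mismatch"] = pd.crosstab(
            truth_mm.rename("true_mismatch"), males["mito_mismatch"].rename("called")
        )
    return out
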