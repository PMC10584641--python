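"""End-to-end marker evaluation runs.

``evaluate_markers`` drives the full analysis for one or more aligned
barcode datasets: QC, K2P distances, nearest-neighbor identification,
barcoding gaps, per-species summaries, tree-based evaluation (imported
tree or NJ), substitution-saturation testing, species delimitation, the
repository audit, and — with several markers — the Kruskal-Wallis /
Dunn comparison of barcoding gaps.  One TSV per result table plus a
JSON manifest; every output is reproduced byte-identically for the same
inputs, configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import delimitation as delim_mod
from . import discrimination as disc_mod
from . import distances as dist_mod
from . import saturation as sat_mod
from . import seqio
from . import trees as trees_mod

log = logging.getLogger(__name__)


@dataclass
class MarkerInput:
    path: str
    marker: str = "other"
    tree_path: str | None = None  # optional externally inferred tree
    frame_offset: int = 0


@dataclass
class RunConfig:
    markers: list = field(default_factory=list)  # MarkerInput items
    outdir: str = "results"
    seed: int = 0
    model: str = "k2p"
    min_sites: int = 50
    outgroup: tuple = ()
    support_threshold: float = 0.90
    singleton_policy: str = "exclude"
    audit_intra_threshold: float = 0.03
    audit_outlier_threshold: float = 0.10
    n_otu_set: tuple = sat_mod.DEFAULT_N_OTU
    saturation_replicates: int = sat_mod.DEFAULT_REPLICATES
    run_saturation: bool = True
    run_delimitation: bool = True
    ptp_mcmc_steps: int = 0  # 0 = ML only


def _write_tsv(rows, path, float_format="%.6f"):
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
    return str(path)


def evaluate_alignment(aln: seqio.BarcodeAlignment, config: RunConfig,
                       outdir: Path, marker_name: str,
                       tree=None, frame_offset: int = 0) -> dict:
    """All per-marker stages; returns a summary dict and writes TSVs."""
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"marker": marker_name, "n_sequences": len(aln.records),
                     "n_species": len(aln.species()),
                     "alignment_length": aln.length}

    _write_tsv(seqio.qc_report(aln, frame_offset=frame_offset),
               outdir / "qc.tsv")

    dm = dist_mod.distance_matrix(aln, model=config.model,
                                  min_sites=config.min_sites)
    _write_tsv(dm.to_long_rows(config.model), outdir / "distances.tsv")

    assignments = disc_mod.nearest_neighbor(dm)
    _write_tsv(
        [
            {
                "query_id": a.query_id,
                "neighbor_ids": ",".join(a.neighbor_ids),
                "min_distance": a.min_distance,
                "conspecific": a.conspecific,
            }
            for a in assignments
        ],
        outdir / "nn_test.tsv",
    )
    pc = disc_mod.percent_correct(
        assignments, dm.species_of, singleton_policy=config.singleton_policy
    )
    summary["percent_correct"] = round(pc, 2)

    gaps = disc_mod.barcoding_gap(dm)
    _write_tsv(
        [dataclasses.asdict(g) for g in gaps], outdir / "gaps.tsv"
    )
    finite_gaps = [g.gap for g in gaps if g.gap is not None]
    summary["n_gaps"] = len(finite_gaps)
    summary["fraction_positive_gaps"] = (
        round(sum(1 for g in finite_gaps if g > 0) / len(finite_gaps), 4)
        if finite_gaps else None
    )

    _write_tsv(
        [dataclasses.asdict(s) for s in disc_mod.species_summary(dm)],
        outdir / "species_summary.tsv",
    )

    audit_cfg = disc_mod.AuditConfig(
        intra_threshold=config.audit_intra_threshold,
        outlier_threshold=config.audit_outlier_threshold,
    )
    audit = disc_mod.audit_groups(dm, assignments, audit_cfg)
    _write_tsv([dataclasses.asdict(a) for a in audit], outdir / "audit.tsv")
    summary["audit_group_counts"] = {
        str(g): sum(1 for a in audit if a.group == g) for g in (1, 2, 3)
    }

    # --- tree stage: import or build ---------------------------------------
    if tree is None:
        base_dm = dm
        if (~dm.defined_mask()).sum() > dm.n:  # undefined off-diagonal cells
            log.info("%s: undefined K2P cells; building NJ from p-distances",
                     marker_name)
            base_dm = dist_mod.distance_matrix(aln, model="p", min_sites=1)
        tree = trees_mod.nj_tree(base_dm)
        tree_source = "nj"
    else:
        base_dm = dm if not (~dm.defined_mask()).sum() > dm.n else \
            dist_mod.distance_matrix(aln, model="p", min_sites=1)
        tree_source = "imported"
    summary["tree_source"] = tree_source
    rooted = trees_mod.root_with_outgroup(tree, list(config.outgroup))
    trees_mod.write_newick(rooted, outdir / "tree.nwk")

    species_of = dm.species_of
    mono = trees_mod.monophyly_fraction(
        rooted, species_of, outgroup=list(config.outgroup) or None,
        singleton_policy="monophyletic",
    )
    _write_tsv(
        [{"species": sp, "monophyletic": v}
         for sp, v in sorted(mono.monophyletic.items())],
        outdir / "monophyly.tsv",
    )
    summary["fraction_monophyletic"] = round(mono.fraction_monophyletic, 4)

    classes = trees_mod.audit_classes(
        rooted, species_of, support_threshold=config.support_threshold,
        outgroup=list(config.outgroup) or None,
    )
    _write_tsv(
        [
            {
                "species": c.species,
                "class": c.clade_class,
                "support_at_mrca": c.support_at_mrca,
                "clade_species": ";".join(c.clade_species),
            }
            for c in classes
        ],
        outdir / "classes.tsv",
    )
    summary["class_counts"] = {
        str(k): sum(1 for c in classes if c.clade_class == k)
        for k in (1, 2, 3)
    }

    # --- saturation ----------------------------------------------------------
    if config.run_saturation:
        partitions = ["whole"]
        if aln.marker in seqio.CODING_MARKERS:
            partitions += ["pos12", "pos3"]
        sat = sat_mod.saturation_test(
            aln, partitions=partitions, n_otu_set=config.n_otu_set,
            seed=config.seed, n_replicates=config.saturation_replicates,
            frame_offset=frame_offset,
        )
        _write_tsv([dataclasses.asdict(s) for s in sat],
                   outdir / "saturation.tsv")
        profile_rows = []
        for p in partitions:
            profile_rows.extend(
                sat_mod.ts_tv_profile(aln, partition=p,
                                      frame_offset=frame_offset,
                                      min_sites=config.min_sites)
            )
        _write_tsv(profile_rows, outdir / "tstv_profile.tsv")
        summary["saturation_verdicts"] = {
            f"{s.partition}/{s.n_otu}": s.verdict for s in sat
        }

    # --- delimitation ----------------------------------------------------------
    if config.run_delimitation:
        ultra = trees_mod.upgma_tree(base_dm)
        gmyc_res = delim_mod.gmyc_single_threshold(ultra)
        ptp_res = (
            delim_mod.ptp_mcmc(rooted, n_steps=config.ptp_mcmc_steps,
                               seed=config.seed)
            if config.ptp_mcmc_steps > 0
            else delim_mod.ptp_ml(rooted, seed=config.seed)
        )
        rows = []
        for ci, tips in enumerate(gmyc_res.clusters):
            for t in tips:
                rows.append({"tip_id": t, "method": "gmyc",
                             "species_cluster": ci})
        for ci, tips in enumerate(ptp_res.ml_partition):
            for t in tips:
                rows.append({"tip_id": t, "method": "ptp",
                             "species_cluster": ci})
        _write_tsv(rows, outdir / "delimitation.tsv")
        fit_summary = {
            "gmyc": {
                "n_species": gmyc_res.n_species,
                "threshold_height": gmyc_res.threshold_height,
                "lnl_null": gmyc_res.lnl_null,
                "lnl_gmyc": gmyc_res.lnl_gmyc,
                "lr_statistic": gmyc_res.lr_statistic,
                "lr_p": gmyc_res.lr_p,
            },
            "ptp": {
                "n_species": ptp_res.n_species,
                "lnl_ml": ptp_res.lnl_ml,
                "lambda_speciation": ptp_res.lambda_speciation,
                "lambda_coalescent": ptp_res.lambda_coalescent,
                "posterior_mode_n_species": ptp_res.posterior_mode_n_species,
            },
        }
        (outdir / "delimitation.json").write_text(
            json.dumps(fit_summary, indent=2, sort_keys=True) + "\n"
        )
        summary["gmyc_n_species"] = gmyc_res.n_species
        summary["ptp_n_species"] = ptp_res.n_species

    return summary


def evaluate_markers(config: RunConfig, alignments: dict | None = None,
                     trees: dict | None = None) -> dict:
    """Run every marker and the cross-marker comparison.

    ``alignments`` may supply in-memory BarcodeAlignments keyed by marker
    name (the CLI passes paths through ``config.markers`` instead).
    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "barcodegap",
        "version": __version__,
        "seed": config.seed,
        # outdir is wherever this manifest sits; echoing it would make
        # otherwise-identical runs differ byte-wise
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "outdir"
        },
        "markers": {},
        "failed_stage": None,
    }
    inputs = {}
    if alignments:
        for name, aln in alignments.items():
            inputs[name] = (aln, (trees or {}).get(name), 0)
    for mi in config.markers:
        mi = mi if isinstance(mi, MarkerInput) else MarkerInput(**mi)
        aln = seqio.read_alignment(mi.path, marker=mi.marker)
        tr = trees_mod.read_newick(mi.tree_path) if mi.tree_path else None
        inputs[mi.marker] = (aln, tr, mi.frame_offset)
    if not inputs:
        raise ValueError("no marker inputs")

    gap_sets = {}
    try:
        for name, (aln, tr, frame) in inputs.items():
            mdir = outdir / name
            summary = evaluate_alignment(
                aln, config, mdir, name, tree=tr, frame_offset=frame
            )
            manifest["markers"][name] = summary
            dm = dist_mod.distance_matrix(aln, model=config.model,
                                          min_sites=config.min_sites)
            gap_sets[name] = [
                g.gap for g in disc_mod.barcoding_gap(dm) if g.gap is not None
            ]
        if len(inputs) >= 2:
            cmp_res = disc_mod.compare_markers(gap_sets)
            rows = [
                {
                    "test": "kruskal_wallis", "marker_a": "", "marker_b": "",
                    "statistic": cmp_res.kw_chi2, "df": cmp_res.kw_df,
                    "p": cmp_res.kw_p, "p_bonferroni": "",
                }
            ]
            for a, b, z, p_raw, p_bonf in cmp_res.pairwise:
                rows.append(
                    {
                        "test": "dunn", "marker_a": a, "marker_b": b,
                        "statistic": z, "df": "", "p": p_raw,
                        "p_bonferroni": p_bonf,
                    }
                )
            _write_tsv(rows, outdir / "marker_comparison.tsv")
            manifest["marker_comparison"] = {
                "kw_chi2": cmp_res.kw_chi2,
                "kw_df": cmp_res.kw_df,
                "kw_p": cmp_res.kw_p,
            }
        else:
            log.info("single marker: comparison stage skipped")
    except Exception as exc:  # manifest records the failure, then re-raise
        manifest["failed_stage"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        raise
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
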