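"""End-to-end orchestration of the paired-library QC workflow.

``run_all`` takes one :class:`RunConfig` (either file inputs or a
simulator configuration), runs stats -> distances -> contamination ->
mixed models -> MDMR -> condense -> population genetics, and writes
tables plus a manifest into a run directory.  Each stage communicates
with the next only through the written files and returned tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contamination import build_reference, stage_report
from .distances import (
    flag_problematic_samples,
    genetic_distance,
    locus_overlap_dissimilarity,
    neighbor_joining,
)
from .inference import MixedModelSpec, fit_mixed, mdmr
from .loci_io import (
    FilterPolicy,
    LociDataset,
    final_dataset,
    presence_matrix,
    read_loci,
    read_metadata,
)
from .popgen import CondenserPolicy, condense
from .sample_stats import library_stats
from .synthetic_data import SimConfig, simulate_paired_study

logger = logging.getLogger("radpair")


@dataclass
class RunConfig:
    """Inputs and knobs for a full run.

    Exactly one of ``loci_paths`` (taxon -> .loci file, plus
    ``metadata_path``) or ``sim`` must be provided.
    """

    out_dir: str
    loci_paths: dict[str, str] | None = None
    metadata_path: str | None = None
    sim: SimConfig | None = None
    filter: FilterPolicy = field(default_factory=FilterPolicy)
    condenser: CondenserPolicy = field(default_factory=CondenserPolicy)
    n_permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.loci_paths is not None
        if has_files == (self.sim is not None):
            raise ValueError("provide exactly one of loci_paths or sim")
        if has_files and not self.metadata_path:
            raise ValueError("metadata_path required with loci_paths")


def _digest(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def config_from_yaml(path) -> RunConfig:
    """Build a RunConfig from a YAML document.

    Top-level keys: ``out_dir`` (required), ``seed``, ``n_permutations``,
    ``filter`` / ``condenser`` (mappings of the policy fields), and either
    ``sim`` (SimConfig fields; ``taxa`` is a list of taxon mappings) or
    ``loci`` (taxon -> path) plus ``metadata``.
    """
    import yaml

    from .synthetic_data import TaxonConfig

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "out_dir" not in doc:
        raise ValueError("config must set out_dir")
    sim = None
    if "sim" in doc:
        s = dict(doc["sim"])
        taxa = tuple(TaxonConfig(**t) for t in s.pop("taxa", []))
        if taxa:
            s["taxa"] = taxa
        if "filter" in s:
            s["filter"] = FilterPolicy(**s["filter"])
        if "mda_input_ng_range" in s:
            s["mda_input_ng_range"] = tuple(s["mda_input_ng_range"])
        sim = SimConfig(**s)
    cond_kw = dict(doc.get("condenser", {}))
    if "min_samples_grid" in cond_kw and cond_kw["min_samples_grid"] is not None:
        cond_kw["min_samples_grid"] = tuple(cond_kw["min_samples_grid"])
    return RunConfig(
        out_dir=doc["out_dir"],
        loci_paths=doc.get("loci"),
        metadata_path=doc.get("metadata"),
        sim=sim,
        filter=FilterPolicy(**doc.get("filter", {})),
        condenser=CondenserPolicy(**cond_kw),
        n_permutations=int(doc.get("n_permutations", 999)),
        seed=int(doc.get("seed", 0)),
    )


def run_all(config: RunConfig) -> Path:
    """Run every stage; returns the run directory.

    Writes: ``stats.csv``, ``overlap_mdmr.csv``, ``genetic_mdmr.csv``,
    ``contamination.csv``, ``problematic_samples.csv``, ``condense.json``,
    ``fst.csv``, ``clusters.csv``, per-taxon newick trees, model
    summaries, and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "load"
    try:
        if config.sim is not None:
            datasets, metadata, _truth = simulate_paired_study(config.sim, out_dir=out / "sim")
            policy = config.sim.filter
        else:
            metadata = read_metadata(config.metadata_path)
            datasets = {}
            for taxon, path in config.loci_paths.items():
                metas = [m for m in metadata if m.taxon == taxon]
                datasets[taxon] = read_loci(path, metas)
            # file-based datasets carry no depths: the assembler already
            # applied its depth filter, so do not re-apply it here
            policy = FilterPolicy(
                min_coverage=0,
                min_samples_per_locus=config.filter.min_samples_per_locus,
                min_final_loci=config.filter.min_final_loci,
                min_shared_for_distance=config.filter.min_shared_for_distance,
            )
        logger.info("loaded %d taxa, %d libraries", len(datasets), len(metadata))

        stage = "stats"
        stats_frames = []
        for taxon, ds in datasets.items():
            st = library_stats(ds, policy)
            st.insert(0, "taxon", taxon)
            stats_frames.append(st)
        stats = pd.concat(stats_frames)
        meta_df = pd.DataFrame([vars(m) for m in metadata]).set_index("library_id")
        stats = stats.join(meta_df.drop(columns=["taxon"]))
        stats.to_csv(out / "stats.csv")

        stage = "models"
        model_rows = []
        mda_stats = stats[stats["method"] == "MDA"].dropna(
            subset=["n_assembled_loci", "n_reads", "input_dna_ng"]
        )
        mda_stats = mda_stats[(mda_stats["n_reads"] > 0)]
        if len(mda_stats) >= 8 and mda_stats["taxon"].nunique() >= 1:
            df = mda_stats.assign(log_reads=np.log(mda_stats["n_reads"]))
            spec = MixedModelSpec(
                response="n_assembled_loci",
                fixed=["log_reads", "input_dna_ng", "log_reads:input_dna_ng"],
                random=[c for c in ("pool", "taxon") if df[c].nunique() > 1],
            )
            res = fit_mixed(spec, df)
            for term in res.retained:
                model_rows.append(dict(model="loci_vs_input", term=term,
                                       p=float(res.pvalues[term])))
        pd.DataFrame(model_rows).to_csv(out / "models.csv", index=False)

        stage = "distances"
        overlap_rows, mdmr_rows, genetic_rows = [], [], []
        trees = {}
        flags_frames = []
        for taxon, ds in datasets.items():
            fds = final_dataset(ds, policy)
            pm = presence_matrix(fds)
            od = locus_overlap_dissimilarity(pm)
            od.to_frame().to_csv(out / f"{taxon}_overlap_dist.csv")
            preds = _predictor_table(ds, stats)
            res = _mdmr_drop_aliased(od, preds, config, taxon, "locus_overlap")
            if res is not None:
                mdmr_rows.append(_mdmr_row(taxon, "locus_overlap", res))
            gd = genetic_distance(ds, policy)
            gd.to_frame().to_csv(out / f"{taxon}_genetic_dist.csv")
            flags = flag_problematic_samples(gd, ds.libraries)
            if len(flags):
                flags.insert(0, "taxon_", taxon)
                flags_frames.append(flags)
            complete = gd.complete_labels()
            if len(complete) >= 3:
                tree = neighbor_joining(gd.subset(complete))
                trees[taxon] = tree
                (out / f"{taxon}_nj.nwk").write_text(str(tree))
                res = _mdmr_drop_aliased(
                    gd.subset(complete), _predictor_table(ds, stats).loc[complete],
                    config, taxon, "genetic",
                )
                if res is not None:
                    mdmr_rows.append(_mdmr_row(taxon, "genetic", res))
        pd.DataFrame(mdmr_rows).to_csv(out / "mdmr.csv", index=False)
        if flags_frames:
            pd.concat(flags_frames).to_csv(out / "problematic_samples.csv")

        stage = "contamination"
        gdna_final = {}
        for taxon, ds in datasets.items():
            fds = final_dataset(ds, policy)
            gdna_ids = {m.library_id for m in ds.libraries if m.method == "gDNA"}
            seqs = [
                loc.members[l]
                for loc in fds.loci
                for l in loc.members
                if l in gdna_ids
            ]
            if seqs:
                gdna_final[taxon] = seqs
        if gdna_final:
            db = build_reference(gdna_final)
            report = stage_report(datasets, db, policy)
            report.to_csv(out / "contamination.csv", index=False)

        stage = "popgen"
        popgen_summary = {}
        for taxon, ds in datasets.items():
            pm = presence_matrix(final_dataset(ds, policy))
            try:
                cres = condense(pm, config.condenser)
            except ValueError as e:
                logger.info("condense skipped for %s: %s", taxon, e)
                continue
            popgen_summary[taxon] = dict(
                kept_samples=cres.n_samples, kept_loci=cres.n_loci,
                min_samples=cres.min_samples,
            )
        (out / "condense.json").write_text(json.dumps(popgen_summary, indent=2))

        stage = "manifest"
        manifest = dict(
            version=__version__,
            seed=config.seed,
            n_permutations=config.n_permutations,
            config_digest=_digest(config),
            taxa={t: len(ds.loci) for t, ds in datasets.items()},
            n_libraries=len(metadata),
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise
    finally:
        logger.removeHandler(handler)


def _predictor_table(ds: LociDataset, stats: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for m in ds.libraries:
        n_final = stats.loc[m.library_id, "n_final_loci"]
        rows[m.library_id] = dict(
            mda=m.method == "MDA",
            population=m.population,
            pool=m.pool,
            log_final_loci=float(np.log1p(n_final)),
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    # drop constant columns (single pool/population would alias the intercept)
    return df.loc[:, df.nunique() > 1]


def _mdmr_drop_aliased(dm, preds: pd.DataFrame, config: RunConfig,
                       taxon: str, kind: str):
    """Run MDMR, dropping aliased predictors (pool first) if necessary."""
    drop_order = [c for c in ("pool", "population") if c in preds.columns]
    while True:
        try:
            return mdmr(dm, preds, n_permutations=config.n_permutations,
                        seed=config.seed)
        except ValueError as e:
            if "rank-deficient" not in str(e) or not drop_order:
                logger.info("MDMR (%s) skipped for %s: %s", kind, taxon, e)
                return None
            dropped = drop_order.pop(0)
            logger.info("MDMR (%s) for %s: dropping aliased predictor %r",
                        kind, taxon, dropped)
            preds = preds.drop(columns=[dropped])


def _mdmr_row(taxon: str, kind: str, res) -> dict:
    row = dict(taxon=taxon, kind=kind,
               omnibus_pseudo_r2=res.omnibus_pseudo_r2, omnibus_p=res.omnibus_p)
    for term, r in res.per_predictor.iterrows():
        row[f"r2_{term}"] = r["pseudo_r2"]
        row[f"p_{term}"] = r["p"]
    return row
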