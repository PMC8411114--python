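"""End-to-end orchestration of the analysis stages.

Stages (in order): simulate (optional) -> read -> quality/class-I filters
-> multiplicity expansion -> log2 + median normalization -> per-condition
pairwise matrices -> valid-value filter -> mixed-model differential tables
-> exclusive events -> temporal/reciprocity classification -> k-of-6
selection -> ward.D2 clustering -> KSEA -> gene-set overrepresentation.

Every stage persists its outputs as TSV under the output directory, so the
CLI's per-stage subcommands can resume from a previous stage's files; a
machine-readable run report (JSON) records configuration, counts and
internal consistency checks.  Identical config + seed yields identical
output bytes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from . import events as ev
from . import preprocess as pp
from . import diffreg, temporal, cluster, ksea
from .errors import ConfigError, PhoscaleError
from .simulate import SimConfig, simulate_experiment, config_to_dict

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "class1_threshold": 0.75,
    "fdr_threshold": 0.01,
    "k_of_6": 4,
    "n_clusters": 2,
    "min_substrates": 1,
    "ksea_background": "regulated_only",  # or "all_tested"
    "temporal_preset": "default",
    "exclusive_strict": False,
    "organism": "rat",
    "protein_diff": True,
    "min_cluster_observed": 2,
}

EVENT_INDEX = ["protein", "position", "residue", "multiplicity"]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(path_or_dict or {})
    cfg.setdefault("params", {})
    unknown = set(cfg["params"]) - set(DEFAULT_PARAMS)
    if unknown:
        raise ConfigError(f"unknown params: {sorted(unknown)}")
    cfg["params"] = {**DEFAULT_PARAMS, **cfg["params"]}
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs either a 'simulate' block or an 'inputs' block")
    return cfg


@dataclass
class RunReport:
    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)
    consistency: dict = field(default_factory=dict)

    def check_consistency(self) -> None:
        """regulated <= tested <= expanded <= parsed, per condition."""
        ok = True
        expanded = self.counts.get("events_expanded")
        parsed = self.counts.get("site_rows_parsed")
        if expanded is not None and parsed is not None:
            # expansion can multiply rows by up to 3 multiplicity slots
            ok &= expanded <= 3 * parsed
        for c, cc in self.counts.get("per_condition", {}).items():
            ok &= cc["regulated"] <= cc["tested"]
            if expanded is not None:
                ok &= cc["tested"] <= expanded
        self.consistency["counts_ordered"] = bool(ok)
        if not ok:
            raise PhoscaleError("run report consistency check failed")

    @staticmethod
    def _jsonable(obj):
        if isinstance(obj, dict):
            return {str(k): RunReport._jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [RunReport._jsonable(v) for v in obj]
        return obj

    def write(self, path: Path) -> None:
        self.check_consistency()
        payload = {
            "config": self.config,
            "counts": self.counts,
            "seeds": self.seeds,
            "versions": self.versions,
            "timestamps": self.timestamps,
            "consistency": self.consistency,
        }
        path.write_text(json.dumps(self._jsonable(payload), indent=2, sort_keys=True, default=str))


class PipelineRun:
    """Stateful runner: stages read/write files under ``outdir``."""

    def __init__(self, config, outdir: str | Path, seed: int | None = None):
        self.config = load_config(config)
        self.params = self.config["params"]
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = seed
        self.report = RunReport(
            config=self.config,
            versions={"phoscale": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        )
        self.report.timestamps["started"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        if seed is not None:
            self.report.seeds["cli"] = seed

    # -- helpers ------------------------------------------------------------

    def _input_paths(self) -> dict:
        if "inputs" in self.config:
            return dict(self.config["inputs"])
        d = self.outdir / "inputs"
        return {
            "sites": d / "phospho_sites.tsv",
            "proteins": d / "protein_groups.tsv",
            "design": d / "design.tsv",
            "kinase_substrate": d / "kinase_substrate.tsv",
            "gene_sets": d / "gene_sets.gmt",
        }

    def _write(self, frame: pd.DataFrame, name: str, index: bool = True) -> None:
        pio.write_table(frame.reset_index() if index else frame, self.outdir / name)

    def _read_indexed(self, name: str) -> pd.DataFrame:
        return pio.read_table(self.outdir / name, index_col=list(range(len(EVENT_INDEX))))

    # -- stages -------------------------------------------------------------

    def stage_simulate(self):
        if "simulate" not in self.config:
            raise ConfigError("no 'simulate' block in config")
        block = dict(self.config["simulate"])
        with_ks = block.pop("with_kinase_substrate", False)
        with_gmt = block.pop("with_gene_sets", False)
        if self.seed is not None:
            block["seed"] = self.seed
        if "profile_mix" in block:
            # YAML parses a bare `null:` key as None; it means the null profile
            block["profile_mix"] = {
                ("null" if k is None else str(k)): float(v) for k, v in block["profile_mix"].items()
            }
        if "multiplicity_probs" in block:
            block["multiplicity_probs"] = tuple(block["multiplicity_probs"])
        sim_config = SimConfig(**block)
        result = simulate_experiment(sim_config, self.outdir / "inputs")
        rng = np.random.default_rng(sim_config.seed + 1)
        if with_ks:
            from .simulate import simulate_kinase_substrate_table

            relations = simulate_kinase_substrate_table(result.truth, rng=rng)
            pio.write_kinase_substrate_table(relations, self.outdir / "inputs" / "kinase_substrate.tsv")
        if with_gmt:
            from .simulate import simulate_gene_sets

            sets = simulate_gene_sets(result.truth, rng=rng)
            pio.write_gene_sets(sets, self.outdir / "inputs" / "gene_sets.gmt")
        self.report.seeds["simulate"] = sim_config.seed
        self.report.config["simulate_resolved"] = config_to_dict(sim_config)
        self.report.counts["simulated_truth_events"] = int(len(result.truth))
        return result

    def stage_preprocess(self):
        paths = self._input_paths()
        design = pio.read_design(paths["design"])
        records = pio.read_phospho_sites(paths["sites"], design)
        self.report.counts["site_rows_parsed"] = len(records)
        records, qrep = ev.filter_quality(records)
        self.report.counts["quality_removed"] = {
            "reverse": qrep.n_reverse, "contaminant": qrep.n_contaminant,
        }
        records, crep = ev.filter_class1(records, self.params["class1_threshold"])
        self.report.counts["class_breakdown"] = {
            "class1": crep.n_class1, "class2": crep.n_class2, "class3": crep.n_class3,
        }
        events = ev.expand_multiplicity(records)
        self.report.counts["events_expanded"] = len(events)
        frame = ev.events_to_frame(events, design)
        normalized = pp.log2_median_normalize(frame)
        self._write(normalized, "events.tsv")
        genes = ev.event_genes(events)
        self._write(genes.to_frame(), "event_genes.tsv")

        exclusive = pp.detect_exclusive(normalized, design, strict=self.params["exclusive_strict"])
        excl_frame = pd.DataFrame(
            [(*key, c[0], c[1]) for key, c in exclusive],
            columns=EVENT_INDEX + ["treatment", "timepoint"],
        )
        self._write(excl_frame, "exclusive.tsv", index=False)
        self.report.counts["exclusive_events"] = len(exclusive)
        return normalized, design, genes, exclusive

    def _load_preprocessed(self):
        normalized = self._read_indexed("events.tsv")
        paths = self._input_paths()
        design = pio.read_design(paths["design"])
        genes = self._read_indexed("event_genes.tsv")["gene_name"]
        excl = pio.read_table(self.outdir / "exclusive.tsv")
        exclusive = [
            (tuple(r[c] for c in EVENT_INDEX), (r["treatment"], r["timepoint"]))
            for _, r in excl.iterrows()
        ]
        return normalized, design, genes, exclusive

    def stage_diffreg(self, normalized=None, design=None, exclusive=None):
        if normalized is None:
            normalized, design, _, exclusive = self._load_preprocessed()
        excl_keys = {key for key, _ in exclusive}
        tested_frame = normalized.loc[[k not in excl_keys for k in normalized.index]]
        per_condition = {}
        diff_tables = {}
        for c in pp.CONDITIONS:
            matrix = pp.build_pair_matrix(tested_frame, design, c)
            matrix, vrep = pp.valid_value_filter(matrix)
            table = diffreg.differential_table(matrix, self.params["fdr_threshold"])
            diff_tables[c] = table
            self._write(table, f"diff_{c[0]}_{c[1]}.tsv")
            per_condition["%s_%s" % c] = {
                "valid": vrep.n_out,
                "tested": int((~table["untestable"]).sum()),
                "regulated": int(table["regulated"].sum()),
                "fail_bio_coverage": vrep.n_fail_bio_coverage,
                "fail_half_valid": vrep.n_fail_half_valid,
            }
        self.report.counts["per_condition"] = per_condition

        if self.params["protein_diff"]:
            paths = self._input_paths()
            if Path(paths.get("proteins", "")).exists():
                self._protein_diff(design, paths)
        return diff_tables

    def _protein_diff(self, design, paths):
        records = pio.read_protein_groups(paths["proteins"], design)
        records = [
            r for r in records
            if not (r.reverse_flag or r.contaminant_flag or r.only_by_site_flag)
            and r.unique_peptides >= 1
        ]
        index = pd.Index([r.protein for r in records], name="protein")
        sample_order = [d.sample_id for d in design]
        mat = np.full((len(records), len(sample_order)), np.nan)
        pos = {sid: j for j, sid in enumerate(sample_order)}
        for i, r in enumerate(records):
            for sid, val in r.lfq_intensities.items():
                mat[i, pos[sid]] = val
        frame = pp.log2_median_normalize(pd.DataFrame(mat, index=index, columns=sample_order))
        for c in pp.CONDITIONS:
            matrix = pp.build_pair_matrix(frame, design, c)
            matrix, _ = pp.valid_value_filter(matrix)
            table = diffreg.differential_table(matrix, self.params["fdr_threshold"])
            pio.write_table(table.reset_index(), self.outdir / f"protein_diff_{c[0]}_{c[1]}.tsv")

    def _load_diff_tables(self, prefix: str = "diff") -> dict:
        tables = {}
        for c in pp.CONDITIONS:
            path = self.outdir / f"{prefix}_{c[0]}_{c[1]}.tsv"
            if path.exists():
                t = pio.read_table(path, index_col=list(range(4 if prefix == "diff" else 1)))
                tables[c] = t
        return tables

    def stage_classify(self, diff_tables=None):
        if diff_tables is None:
            diff_tables = self._load_diff_tables()
        preset = self.params["temporal_preset"]
        calls = {}
        for trt in ("bic", "ttx"):
            calls[trt] = temporal.temporal_calls(diff_tables, trt, preset)
            self._write(calls[trt], f"temporal_{trt}.tsv")
        rec_table, summaries = temporal.overlap_reciprocity(calls["bic"], calls["ttx"])
        rec_out = rec_table.copy()
        if len(rec_out):
            keys = pd.DataFrame(rec_out["key"].tolist(), columns=EVENT_INDEX)
            rec_out = pd.concat([keys, rec_out.drop(columns="key")], axis=1)
        else:
            rec_out = pd.DataFrame(columns=EVENT_INDEX + ["phase", "direction_bic", "direction_ttx", "reciprocal"])
        self._write(rec_out, "reciprocity.tsv", index=False)
        summary = pd.DataFrame(
            [
                {"phase": s.phase, "n_overlap": s.n_overlap, "n_reciprocal": s.n_reciprocal,
                 "pct_reciprocal": s.pct_reciprocal}
                for s in summaries
            ]
        )
        self._write(summary, "reciprocity_summary.tsv", index=False)
        self.report.counts["temporal"] = {
            trt: calls[trt]["temporal_class"].value_counts().to_dict() for trt in calls
        }
        self.report.counts["reciprocity"] = {
            s.phase: {"overlap": s.n_overlap, "reciprocal": s.n_reciprocal} for s in summaries
        }

        selected = temporal.select_k_of_6(diff_tables, self.params["k_of_6"])
        sel_frame = pd.DataFrame(selected, columns=EVENT_INDEX)
        self._write(sel_frame, "k_of_6.tsv", index=False)
        self.report.counts["k_of_6_selected"] = len(selected)

        protein_tables = self._load_diff_tables("protein_diff")
        if protein_tables:
            rows = []
            for c in pp.CONDITIONS:
                frac = temporal.phospho_protein_overlap(diff_tables[c], protein_tables[c])
                rows.append({"treatment": c[0], "timepoint": c[1], "fraction_protein_regulated": frac})
            self._write(pd.DataFrame(rows), "phospho_protein_overlap.tsv", index=False)
        return calls, rec_table, selected

    def stage_cluster(self, diff_tables=None, selected=None):
        if diff_tables is None:
            diff_tables = self._load_diff_tables()
        if selected is None:
            sel = pio.read_table(self.outdir / "k_of_6.tsv")
            selected = [tuple(r) for r in sel.itertuples(index=False)]
        if len(selected) < 2:
            logger.warning("fewer than 2 selected events; skipping clustering")
            return None
        fc = pd.DataFrame(
            {
                "%s_%s" % c: diff_tables[c]["log2fc"].reindex(pd.MultiIndex.from_tuples(selected, names=EVENT_INDEX))
                for c in pp.CONDITIONS
            }
        )
        fc.index = pd.MultiIndex.from_tuples(selected, names=EVENT_INDEX)
        fc, excluded = cluster.filter_min_observed(fc, self.params["min_cluster_observed"])
        self._write(fc, "fold_change_matrix.tsv")
        D = cluster.euclidean_distance_na(fc)
        dend = cluster.ward_d2_linkage(D)
        self._write(cluster.linkage_frame(dend), "linkage.tsv", index=False)
        labels = cluster.cut_clusters(dend, min(self.params["n_clusters"], len(fc)))
        lab_frame = fc.reset_index()[EVENT_INDEX]
        lab_frame["cluster"] = labels
        self._write(lab_frame, "clusters.tsv", index=False)
        self.report.counts["clustered_events"] = int(len(fc))
        self.report.counts["cluster_rows_excluded"] = len(excluded)
        return dend, labels, fc

    def stage_ksea(self, diff_tables=None):
        paths = self._input_paths()
        ks_path = paths.get("kinase_substrate")
        if not ks_path or not Path(ks_path).exists():
            logger.info("no kinase-substrate table configured; skipping KSEA")
            return None
        if diff_tables is None:
            diff_tables = self._load_diff_tables()
        relations = pio.read_kinase_substrate_table(ks_path, self.params["organism"])
        genes = self._read_indexed("event_genes.tsv")["gene_name"]
        results = {}
        for c, table in diff_tables.items():
            if self.params["ksea_background"] == "regulated_only":
                subset = table[table["regulated"].astype(bool)]
            else:
                subset = table[~table["untestable"]]
            if len(subset) < 3:
                continue
            smap = ksea.map_substrates(subset["log2fc"], genes, relations)
            try:
                scores = ksea.kinase_zscore(smap, self.params["min_substrates"])
            except PhoscaleError:
                continue
            results[c] = scores
            pio.write_table(scores, self.outdir / f"ksea_{c[0]}_{c[1]}.tsv")
        self.report.counts["ksea_conditions"] = len(results)
        return results

    def stage_enrich(self, diff_tables=None):
        paths = self._input_paths()
        gmt_path = paths.get("gene_sets")
        if not gmt_path or not Path(gmt_path).exists():
            logger.info("no gene sets configured; skipping enrichment")
            return None
        if diff_tables is None:
            diff_tables = self._load_diff_tables()
        gene_sets = pio.read_gene_sets(gmt_path)
        genes = self._read_indexed("event_genes.tsv")["gene_name"]
        background = {str(g).casefold() for g in genes} - {""}
        n_enriched = 0
        for c, table in diff_tables.items():
            results = ksea.enrich_by_direction(
                table, genes, gene_sets, background, fdr=self.params["fdr_threshold"]
            )
            for direction, res in results.items():
                pio.write_table(res, self.outdir / f"enrichment_{c[0]}_{c[1]}_{direction}.tsv")
                if len(res):
                    n_enriched += int(res["enriched"].sum())
        self.report.counts["enriched_terms"] = n_enriched
        return n_enriched

    def finalize(self) -> RunReport:
        self.report.timestamps["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.report.write(self.outdir / "run_report.json")
        return self.report


def run_pipeline(config, outdir: str | Path, seed: int | None = None) -> RunReport:
    """Execute every configured stage end-to-end; returns the run report."""
    run = PipelineRun(config, outdir, seed=seed)
    if "simulate" in run.config:
        run.stage_simulate()
    normalized, design, genes, exclusive = run.stage_preprocess()
    diff_tables = run.stage_diffreg(normalized, design, exclusive)
    calls, rec_table, selected = run.stage_classify(diff_tables)
    run.stage_cluster(diff_tables, selected)
    run.stage_ksea(diff_tables)
    run.stage_enrich(diff_tables)
    return run.finalize()
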