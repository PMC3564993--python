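"""End-to-end orchestration: manifest -> filtered dataset -> report bundle.

The report mirrors a classical multilocus polymorphism study: a per-locus
polymorphism table (length, site counts, S, pi and theta_W by category,
Tajima's D on silent sites, ENC, GC3), a SNP table, the frequency-stratified
theta_n/theta_si ratio ladder, folded site-frequency spectra with their
neutral Wright-Fisher expectation, per-SNP F_ST overall and between basins,
the DFE partition with the segregating-load chain, diversity/codon-bias
correlation diagnostics, and a log of every filter and clamping event.

Reports are deterministic: same inputs and configuration give byte-identical
output files, independent of locus order in the manifest and of individual
order within FASTA files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import dfe_load as dl
from . import diversity as dv
from .io_model import Dataset, apply_locus_filters, load_dataset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis configuration; every field is echoed into the report."""

    manifest: str = ""
    populations: str = ""
    exclude_mitochondrial: bool = True
    exclude_locus_ids: list[str] = field(default_factory=list)
    f0_source: str = "gt02"  # 'gt02' | 'shared'
    genome_nonsyn_sites: float = 1e7
    map_length_cM: float = 575.0
    multiple_testing: str = "bonferroni"  # 'bonferroni' | 'benjamini-hochberg'
    tajima_pvalue_reps: int = 0  # 0 disables the conditional-coalescent p-values
    outdir: str = "polyload_report"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ReportBundle:
    config: RunConfig
    per_locus: pd.DataFrame
    diversity: pd.DataFrame
    snps: pd.DataFrame
    ratios: dict
    sfs: pd.DataFrame
    fst: pd.DataFrame
    dfe_load: dict
    correlations: dict
    events: list[str]
    summaries: list[dv.LocusSummary] = field(default_factory=list, repr=False)


def _per_locus_table(summaries: Sequence[dv.LocusSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "locus_id": s.locus_id,
                "n_individuals": s.n_individuals,
                "n_chromosomes": s.n,
                "length": s.length,
                "coding_sites": s.sites["syn"] + s.sites["nonsyn"],
                "syn_sites": s.sites["syn"],
                "nonsyn_sites": s.sites["nonsyn"],
                "noncoding_sites": s.sites["noncoding"],
                "S_syn": s.S["syn"],
                "S_nonsyn": s.S["nonsyn"],
                "S_noncoding": s.S["noncoding"],
                "S_silent": s.S["silent"],
                "S_total": s.S["all"],
                "pi_syn": s.pi_per_site("syn"),
                "pi_nonsyn": s.pi_per_site("nonsyn"),
                "pi_noncoding": s.pi_per_site("noncoding"),
                "pi_silent": s.pi_per_site("silent"),
                "theta_syn": s.theta_w("syn"),
                "theta_nonsyn": s.theta_w("nonsyn"),
                "theta_noncoding": s.theta_w("noncoding"),
                "theta_silent": s.theta_w("silent"),
                "tajima_d_silent": s.tajima_d_silent(),
                "enc": s.enc,
                "gc3": s.gc3,
                "n_triallelic": s.n_triallelic,
            }
        )
    return pd.DataFrame(rows)


def _snp_table(snps: Sequence[dv.SnpRecord], basins: dict[str, str]) -> pd.DataFrame:
    rows = []
    for s in snps:
        rows.append(
            {
                "locus_id": s.locus_id,
                "pos_1based": s.position + 1,
                "major": s.major,
                "minor": s.minor,
                "effect": s.effect,
                "n": s.n,
                "mac": s.mac,
                "maf": round(s.maf, 6),
                "class": s.frequency_class,
                "singleton": s.singleton,
                "shared_pops": s.shared_between_populations,
                "shared_basins": s.shared_between_basins(basins),
                "fst": None if s.fst is None or np.isnan(s.fst) else round(s.fst, 6),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["locus_id", "pos_1based"]).reset_index(drop=True)
    return df


def _sfs_table(snps: Sequence[dv.SnpRecord]) -> pd.DataFrame:
    """Observed folded spectra by effect category, in the three MAF classes,
    with the Wright-Fisher expectation (scaled to the silent total)."""
    rows = []
    groups = {
        "nonsynonymous": [s for s in snps if s.effect == "nonsynonymous"],
        "silent": [s for s in snps if s.effect != "nonsynonymous"],
    }
    for name, group in groups.items():
        binned = {c: 0 for c in dv.MAF_CLASSES}
        for s in group:
            binned[s.frequency_class] += 1
        rows.append({"category": name, **binned, "total": len(group)})
    # neutral expectation, per locus sample size, scaled to each group total
    for name, group in groups.items():
        if not group:
            continue
        exp = {c: 0.0 for c in dv.MAF_CLASSES}
        by_n: dict[int, int] = {}
        for s in group:
            by_n[s.n] = by_n.get(s.n, 0) + 1
        for n, count in sorted(by_n.items()):
            spectrum = dv.expected_wf_folded_sfs(n, count)
            for c, v in dv.bin_sfs_by_maf(spectrum, n).items():
                exp[c] += v
        rows.append({"category": f"wf_expected_{name}", **{k: round(v, 3) for k, v in exp.items()},
                     "total": len(group)})
    return pd.DataFrame(rows)


def _fst_table(snps: Sequence[dv.SnpRecord], basins: dict[str, str]) -> pd.DataFrame:
    """Per-effect-category mean per-SNP F_ST, among all populations and
    between basins (populations pooled within basin)."""
    rows = []
    for scope in ("populations", "basins"):
        for cat_name, pred in (("nonsynonymous", lambda s: s.effect == "nonsynonymous"),
                               ("silent", lambda s: s.effect != "nonsynonymous")):
            vals = []
            for s in snps:
                if not pred(s):
                    continue
                if scope == "populations":
                    v = s.fst
                else:
                    by_basin: dict[str, list[float]] = {}
                    for pop, minor in s.pop_minor_counts.items():
                        b = basins.get(pop)
                        if b is None:
                            continue
                        by_basin.setdefault(b, [0, 0])
                        by_basin[b][0] += minor
                        by_basin[b][1] += s.pop_chromosomes[pop] - minor
                    if len(by_basin) < 2:
                        continue
                    counts = np.array([by_basin[b] for b in sorted(by_basin)])
                    try:
                        v = dv.fst_weir_cockerham(counts)
                    except ValueError:
                        v = None
                if v is not None and not np.isnan(v):
                    vals.append(v)
            rows.append(
                {
                    "scope": scope,
                    "category": cat_name,
                    "n_snps": len(vals),
                    "mean_fst": float(np.mean(vals)) if vals else None,
                    "median_fst": float(np.median(vals)) if vals else None,
                }
            )
    return pd.DataFrame(rows)


def _correlations(summaries: Sequence[dv.LocusSummary]) -> dict:
    """Pearson r (two-sided p) of per-locus theta_s, theta_nc, theta_n
    against ENC — a computed diagnostic for codon-bias confounding."""
    out = {}
    for cat, key in (("syn", "theta_s_vs_enc"), ("noncoding", "theta_nc_vs_enc"), ("nonsyn", "theta_n_vs_enc")):
        xs, ys = [], []
        for s in summaries:
            th = s.theta_w(cat)
            if th is not None and s.enc is not None:
                xs.append(th)
                ys.append(s.enc)
        if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
            r, p = stats.pearsonr(xs, ys)
            out[key] = {"r": float(r), "p": float(p), "n_loci": len(xs)}
        else:
            out[key] = {"r": None, "p": None, "n_loci": len(xs)}
    return out


class _EventLog(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.INFO)
        self.events: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.events.append(f"{record.levelname}: {record.getMessage()}")


def analyze_dataset(dataset: Dataset, config: RunConfig | None = None) -> ReportBundle:
    """Run the full analysis on an in-memory dataset.

    The dataset is filtered per the configuration, loci are processed in
    locus-id order (report output is invariant to input ordering), and every
    filter/clamping event is collected into the bundle.
    """
    config = config or RunConfig()
    handler = _EventLog()
    plogger = logging.getLogger("polyload")
    old_level = plogger.level
    if plogger.getEffectiveLevel() > logging.INFO:
        plogger.setLevel(logging.INFO)
    plogger.addHandler(handler)
    try:
        filtered = apply_locus_filters(
            dataset, config.exclude_mitochondrial, config.exclude_locus_ids
        ).sorted()
        if not filtered.loci:
            raise ValueError("no loci retained after filtering")
        summaries = []
        for aln in filtered.loci:
            try:
                summaries.append(dv.analyze_locus(aln, filtered.basins))
            except ValueError as exc:
                log.warning("locus %s skipped: %s", aln.locus_id, exc)
        if not summaries:
            raise ValueError("no analyzable loci")
        snps = [s for summ in summaries for s in summ.snps]
        per_locus = _per_locus_table(summaries)
        div = dv.diversity_table(summaries)
        snp_df = _snp_table(snps, filtered.basins)
        part, load, ratios = dl.dfe_load_analysis(
            summaries,
            snps,
            filtered.basins,
            f0_source=config.f0_source,
            genome_nonsyn_sites=config.genome_nonsyn_sites,
            map_length_cM=config.map_length_cM,
        )
        ratios = dict(ratios)
        ratios["theta_n_over_theta_s_synonymous_only"] = dl.synonymous_only_ratio(snps, summaries)
        dfe_dict = {
            "partition": dataclasses.asdict(part),
            "load": dataclasses.asdict(load),
            "ratios": ratios,
        }
        if config.tajima_pvalue_reps > 0:
            _add_tajima_pvalues(per_locus, summaries, config)
        bundle = ReportBundle(
            config=config,
            per_locus=per_locus,
            diversity=div,
            snps=snp_df,
            ratios=ratios,
            sfs=_sfs_table(snps),
            fst=_fst_table(snps, filtered.basins),
            dfe_load=dfe_dict,
            correlations=_correlations(summaries),
            events=handler.events,
            summaries=summaries,
        )
        return bundle
    finally:
        plogger.removeHandler(handler)
        plogger.setLevel(old_level)


def _add_tajima_pvalues(per_locus: pd.DataFrame, summaries, config: RunConfig) -> None:
    from statsmodels.stats.multitest import multipletests

    pvals, idx = [], []
    for i, s in enumerate(summaries):
        d = s.tajima_d_silent()
        if d is None:
            continue
        rng = np.random.default_rng((config.seed, i))
        pvals.append(dv.tajima_d_pvalue(d, s.n, s.S["silent"], config.tajima_pvalue_reps, rng))
        idx.append(i)
    col_p = [None] * len(summaries)
    col_adj = [None] * len(summaries)
    if pvals:
        method = "fdr_bh" if config.multiple_testing == "benjamini-hochberg" else "bonferroni"
        adj = multipletests(pvals, method=method)[1]
        for j, i in enumerate(idx):
            col_p[i] = pvals[j]
            col_adj[i] = float(adj[j])
    per_locus["tajima_d_pvalue"] = col_p
    per_locus["tajima_d_pvalue_adj"] = col_adj


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Load inputs per *config*, analyze, and write the report bundle."""
    dataset = load_dataset(config.manifest, config.populations)
    bundle = analyze_dataset(dataset, config)
    write_report(bundle, config.outdir)
    return bundle


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_report(bundle: ReportBundle, outdir: str | Path) -> Path:
    """Write the report: UTF-8 TSV tables, one machine-readable JSON, and a
    deterministic run log (no timestamps)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(bundle.per_locus, outdir / "per_locus.tsv")
    _write_tsv(bundle.diversity, outdir / "diversity.tsv")
    _write_tsv(bundle.snps, outdir / "snps.tsv")
    _write_tsv(bundle.sfs, outdir / "sfs.tsv")
    _write_tsv(bundle.fst, outdir / "fst.tsv")
    report = {
        "config": dataclasses.asdict(bundle.config),
        "ratios": bundle.ratios,
        "dfe_load": bundle.dfe_load,
        "correlations": bundle.correlations,
        "pooled": bundle.diversity[bundle.diversity["locus_id"] == "POOLED"]
        .set_index("category")[["S", "sites", "pi", "theta_w"]]
        .to_dict(orient="index"),
        "events": bundle.events,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
    (outdir / "run.log").write_text("".join(e + "\n" for e in bundle.events))
    return outdir


def category_group_summary(
    summaries: Sequence[dv.LocusSummary],
    snps: Sequence[dv.SnpRecord],
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Pooled theta_n/theta_si per functional-category label.

    *labels* maps locus ids to free-form group labels (e.g. curated gene
    ontology groups); unlabeled loci are pooled as ``unassigned``.  The
    site-weighted combination of disjoint groups reproduces the global
    ratio.
    """
    labels = labels or {}
    groups: dict[str, list] = {}
    for s in summaries:
        groups.setdefault(labels.get(s.locus_id, "unassigned"), []).append(s)
    snps_by_locus: dict[str, list] = {}
    for snp in snps:
        snps_by_locus.setdefault(snp.locus_id, []).append(snp)
    rows = []
    for label in sorted(groups):
        summs = groups[label]
        group_snps = [s for summ in summs for s in snps_by_locus.get(summ.locus_id, [])]
        denom_n, denom_si = dl.ratio_denominators(summs)
        try:
            ratio = dl.theta_ratio(group_snps, denom_n, denom_si)
        except ValueError:
            ratio = None
        rows.append(
            {
                "group": label,
                "n_loci": len(summs),
                "S_nonsyn": sum(s.S["nonsyn"] for s in summs),
                "S_silent": sum(s.S["silent"] for s in summs),
                "theta_ratio": ratio,
            }
        )
    return pd.DataFrame(rows)


def read_group_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"locus_id", "group"}.issubset(df.columns):
        raise ValueError(f"{path}: needs columns ['locus_id', 'group']")
    return dict(zip(df["locus_id"], df["group"]))
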