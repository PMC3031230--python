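"""Stage orchestration: validated configuration, stage runners and
machine-readable run manifests.

Each stage reads its inputs from (and writes its outputs to) a run
directory.  Outputs are written atomically (temp file + rename) and
every stage leaves a ``<stage>.manifest.json`` recording parameters,
input/output checksums and the package version, so a rerun with the
same seed and config is byte-checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from . import differential, enrichment, io, simulate, specificity, timecourse

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_stage", "STAGES"]


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and sizes of the pipeline, with study defaults."""

    seed: int = 1
    raw_min: float = 100.0        # raw-intensity filter (strict >)
    expressed_min: float = -5.0   # 'expressed' call on normalized log2
    entropy_max: float = 4.5      # bits; specificity cutoff (strict <)
    rel_min: float = 8.0          # max relative expression cutoff (strict >)
    fdr: float = 0.05
    fc_diurnal: float = 3.0
    fc_transition: float = 3.0
    fc_fertile_sterile: float = 2.0
    phases_k: int = 3
    clusters_k: int = 7
    refine_n_cut: int = 10
    spike_min_ratio: float = 32.0
    motif: str = "GNATATNC"
    flank: int = 1000
    n_genes: int = 5000

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        for name in ("fc_diurnal", "fc_transition", "fc_fertile_sterile"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.raw_min <= 0 or self.flank <= 0 or self.n_genes <= 0:
            raise ValueError("raw_min, flank and n_genes must be positive")
        if self.phases_k < 2 or self.clusters_k < 1 or self.refine_n_cut < 1:
            raise ValueError("cluster counts must be positive (phases_k >= 2)")
        if self.spike_min_ratio <= 1:
            raise ValueError("spike_min_ratio must exceed 1")
        enrichment.MotifPattern(self.motif)  # validates the IUPAC string

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_mapping(data)


# ---------------------------------------------------------------------------
# atomic writes and manifests


def _atomic_write(path: Path, writer: Callable[[Path], None]) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    _atomic_write(path, lambda p: df.to_csv(p, sep="\t", index=index))


def _write_json(obj, path: Path) -> None:
    _atomic_write(path, lambda p: p.write_text(json.dumps(obj, indent=1,
                                                          default=str)))


def _write_fasta(sequences: dict[str, str], path: Path) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in
               sequences.items()]
    _atomic_write(path, lambda p: SeqIO.write(records, str(p), "fasta"))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest(stage: str, config: PipelineConfig, run_dir: Path,
              inputs: list[Path], outputs: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    path = run_dir / f"{stage}.manifest.json"
    _write_json(manifest, path)
    return path


def _require(run_dir: Path, *names: str) -> list[Path]:
    paths = [run_dir / n for n in names]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError(
            f"missing stage input(s): {missing}; run the producing stage first")
    return paths


def _load_raw(run_dir: Path, name: str) -> io.RawMatrix:
    return io.read_expression_table(run_dir / name)


def _load_meta(run_dir: Path, name: str) -> io.SampleMetadata:
    return io.SampleMetadata.read_tsv(run_dir / name)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, run_dir: Path) -> dict:
    field_cfg = simulate.FieldConfig.scaled(config.n_genes, seed=config.seed)
    raw, meta, truth = simulate.generate_field_transcriptome(field_cfg)
    _write_tsv(raw.values, run_dir / "field_raw.tsv")
    _atomic_write(run_dir / "field_metadata.tsv",
                  lambda p: meta.write_tsv(p))
    tc_cfg = simulate.TimecourseConfig.scaled(config.n_genes,
                                              seed=config.seed + 1)
    tc_raw, tc_meta, tc_truth = simulate.generate_timecourse(tc_cfg)
    _write_tsv(tc_raw.values, run_dir / "timecourse_raw.tsv")
    _atomic_write(run_dir / "timecourse_metadata.tsv",
                  lambda p: tc_meta.write_tsv(p))
    fs_cfg = simulate.FertileSterileConfig.scaled(config.n_genes,
                                                  seed=config.seed + 2)
    fs_raw, fs_meta, fs_truth = simulate.generate_fertile_sterile(fs_cfg)
    _write_tsv(fs_raw.values, run_dir / "fs_raw.tsv")
    _atomic_write(run_dir / "fs_metadata.tsv", lambda p: fs_meta.write_tsv(p))
    n_study = max(20, int(round(333 * config.n_genes / 5000)))
    sequences, study_ids, up_truth = simulate.generate_upstreams(
        n_study=n_study, n_background=config.n_genes - n_study,
        length=config.flank, pattern=config.motif, seed=config.seed + 3)
    _write_fasta({g: sequences[g] for g in study_ids},
                 run_dir / "upstream_study.fasta")
    _write_fasta(sequences, run_dir / "upstream_background.fasta")
    go = simulate.generate_go_fixture(seed=config.seed + 4)
    _write_tsv(go["gene2go"], run_dir / "gene2go.tsv", index=False)
    _write_tsv(go["slim_mapping"], run_dir / "slim_mapping.tsv", index=False)
    _write_json({"study": go["study"], "background": go["background"]},
                run_dir / "go_sets.json")
    _write_json(
        {"field": truth, "timecourse": tc_truth, "fertile_sterile": fs_truth,
         "upstream": up_truth, "go": go["truth"]},
        run_dir / "truth.json",
    )
    return {"n_genes": config.n_genes, "n_field_samples": raw.shape[1],
            "n_timecourse_samples": tc_raw.shape[1],
            "n_fs_samples": fs_raw.shape[1]}


def _stage_normalize(config: PipelineConfig, run_dir: Path) -> dict:
    _require(run_dir, "field_raw.tsv", "field_metadata.tsv")
    raw = _load_raw(run_dir, "field_raw.tsv")
    meta = _load_meta(run_dir, "field_metadata.tsv")
    log2 = io.percentile_normalize(raw)
    quant = io.quantile_normalize(raw)
    _write_tsv(log2.values, run_dir / "field_log2_p75.tsv")
    _write_tsv(quant.values, run_dir / "field_log2_quantile.tsv")
    expressed = io.expressed_flags(log2, meta, threshold=config.expressed_min)
    _write_tsv(expressed.fraction.to_frame("expressed_fraction"),
               run_dir / "expressed_fraction.tsv")
    _write_tsv(pd.DataFrame({"gene_id": expressed.universal}),
               run_dir / "expressed_universal.tsv", index=False)
    means = io.average_replicates(log2, meta)
    _write_tsv(means, run_dir / "field_condition_means.tsv")
    return {"expressed_fraction_min": float(expressed.fraction.min()),
            "expressed_fraction_max": float(expressed.fraction.max()),
            "n_universal": int(len(expressed.universal))}


def _stage_specificity(config: PipelineConfig, run_dir: Path) -> dict:
    _require(run_dir, "field_raw.tsv", "field_metadata.tsv",
             "field_log2_p75.tsv")
    raw = _load_raw(run_dir, "field_raw.tsv")
    meta = _load_meta(run_dir, "field_metadata.tsv")
    quant = io.quantile_normalize(raw)
    cond_means = io.average_replicates(quant, meta)
    weights = specificity.condition_weights(cond_means, mode="linear")
    entropy = specificity.shannon_entropy(weights)
    log2 = io.read_table(run_dir / "field_log2_p75.tsv")
    relmat = io.relative_expression(
        io.ExpressionMatrix(log2, "percentile75"))
    result = specificity.select_specific_genes(
        entropy, relmat, h_max=config.entropy_max, rel_min=config.rel_min,
        n_conditions=cond_means.shape[1])
    spec_genes = result.index[result["specific"]]
    labels = pd.Series(pd.NA, index=result.index, dtype="Int64", name="cluster")
    if len(spec_genes) >= config.clusters_k:
        cl = specificity.cluster_specific_genes(
            relmat.values.loc[spec_genes], k=config.clusters_k)
        labels.loc[cl.labels.index] = cl.labels.astype("Int64")
    out = result.assign(cluster=labels)
    out.index.name = "gene_id"
    _write_tsv(out, run_dir / "specificity.tsv")
    return {"n_specific": int(result["specific"].sum())}


def _organ_slug(organ: str) -> str:
    return organ.replace(" ", "_")


def _stage_diurnal(config: PipelineConfig, run_dir: Path) -> dict:
    _require(run_dir, "field_raw.tsv", "field_metadata.tsv",
             "field_log2_p75.tsv")
    raw = _load_raw(run_dir, "field_raw.tsv")
    meta = _load_meta(run_dir, "field_metadata.tsv")
    keep = io.filter_by_raw_intensity(raw, threshold=config.raw_min)
    log2 = io.read_table(run_dir / "field_log2_p75.tsv").loc[keep]
    summary = {"n_probes_tested": int(len(keep))}
    for organ in ("leaf blade", "leaf sheath", "root", "stem"):
        res = differential.diurnal_extraction(
            log2, meta, organ, fdr_max=config.fdr, fc_min=config.fc_diurnal)
        table = res.table.loc[res.selected]
        table.index.name = "gene_id"
        _write_tsv(table, run_dir / f"diurnal_{_organ_slug(organ)}.tsv")
        summary[f"{_organ_slug(organ)}_day"] = int(len(res.up))
        summary[f"{_organ_slug(organ)}_night"] = int(len(res.down))
        summary[f"{_organ_slug(organ)}_fraction"] = float(
            len(res.selected) / len(keep))
    return summary


def _stage_stagewise(config: PipelineConfig, run_dir: Path) -> dict:
    _require(run_dir, "field_raw.tsv", "field_metadata.tsv",
             "field_log2_p75.tsv")
    raw = _load_raw(run_dir, "field_raw.tsv")
    meta = _load_meta(run_dir, "field_metadata.tsv")
    keep = io.filter_by_raw_intensity(raw, threshold=config.raw_min)
    log2 = io.read_table(run_dir / "field_log2_p75.tsv").loc[keep]
    results = {}
    for organ in ("leaf blade", "leaf sheath", "root"):
        veg = meta.select(organ=organ, stage="vegetative", time_of_day="12:00")
        rep = meta.select(organ=organ, stage="reproductive", time_of_day="12:00")
        results[organ] = differential.extract_de(
            log2, veg, rep, fdr_max=config.fdr, fc_min=config.fc_transition)
    venn = differential.universal_intersection(results)
    regions = {"&".join(k): sorted(v) for k, v in venn.regions.items()}
    _write_json({"regions": regions,
                 "universal": sorted(venn.universal),
                 "concordant": venn.concordant},
                run_dir / "stagewise_venn.json")
    return {"n_universal": len(venn.universal),
            **{f"n_{_organ_slug(o)}": int(len(r.selected))
               for o, r in results.items()}}


def _stage_anova(config: PipelineConfig, run_dir: Path) -> dict:
    _require(run_dir, "field_metadata.tsv", "field_log2_p75.tsv")
    meta = _load_meta(run_dir, "field_metadata.tsv")
    log2 = io.read_table(run_dir / "field_log2_p75.tsv")
    lp = meta.table[meta.table["organ"].isin(["lemma", "palea"])]
    samples = lp["sample_id"].tolist()
    tissue = pd.Series(lp["organ"].to_numpy(), index=samples)
    stage = pd.Series(lp["stage"].to_numpy(), index=samples)
    res = differential.two_way_anova(log2[samples], tissue, stage)
    res.index.name = "gene_id"
    _write_tsv(res, run_dir / "anova_lemma_palea.tsv")
    return {"n_tissue": int((res["q_tissue"] < config.fdr).sum()),
            "n_stage": int((res["q_stage"] < config.fdr).sum()),
            "n_interaction": int((res["q_interaction"] < config.fdr).sum())}


def _timecourse_means(config: PipelineConfig, run_dir: Path):
    raw = _load_raw(run_dir, "timecourse_raw.tsv")
    meta = _load_meta(run_dir, "timecourse_metadata.tsv")
    keep = io.filter_by_raw_intensity(raw, threshold=config.raw_min)
    filtered = io.RawMatrix(raw.values.loc[keep])
    log2 = io.percentile_normalize(filtered)
    means = io.average_replicates(log2, meta)
    return log2, means, meta


def _stage_phases(config: PipelineConfig, run_dir: Path) -> dict:
    _require(run_dir, "timecourse_raw.tsv", "timecourse_metadata.tsv")
    log2, means, meta = _timecourse_means(config, run_dir)
    _write_tsv(log2.values, run_dir / "timecourse_log2.tsv")
    _write_tsv(means, run_dir / "timecourse_condition_means.tsv")
    # transient contamination spikes distort sample correlations; flag
    # and exclude those genes before segmenting (the flagged set itself
    # is reported by the spike stage)
    contamination = timecourse.detect_transient_spike(
        means, min_ratio=config.spike_min_ratio)
    clean = means.drop(index=contamination.all_flagged)
    pcc = timecourse.pcc_matrix(clean)
    seg = timecourse.segment_phases(pcc, k=config.phases_k)
    _write_tsv(pcc, run_dir / "timecourse_pcc.tsv")
    _write_tsv(pd.DataFrame({"timepoint": seg.timepoints,
                             "phase": seg.phase_labels}),
               run_dir / "timecourse_phases.tsv", index=False)
    return {"boundaries": [list(b) for b in seg.boundaries],
            "method": seg.method}


def _transition_conditions(meta: io.SampleMetadata,
                           boundary_dats: tuple[int, int]) -> tuple[list, list]:
    before = meta.select(dat=boundary_dats[0])
    after = meta.select(dat=boundary_dats[1])
    return before, after


def _stage_de(config: PipelineConfig, run_dir: Path) -> dict:
    """Transition DE at the first phase boundary (41 vs 48 DAT)."""
    _require(run_dir, "timecourse_raw.tsv", "timecourse_metadata.tsv",
             "timecourse_phases.tsv")
    log2, means, meta = _timecourse_means(config, run_dir)
    phases = pd.read_csv(run_dir / "timecourse_phases.tsv", sep="\t")
    tps = phases["timepoint"].tolist()
    labels = phases["phase"].tolist()
    b = next(i for i in range(len(tps) - 1) if labels[i] != labels[i + 1])
    t_a, t_b = tps[b], tps[b + 1]
    before, after = _transition_conditions(meta, (int(str(t_a).lstrip("T")),
                                                  int(str(t_b).lstrip("T"))))
    res = differential.extract_de(log2.values, before, after,
                                  fdr_max=config.fdr,
                                  fc_min=config.fc_transition)
    table = res.table.loc[res.selected]
    table.index.name = "gene_id"
    _write_tsv(table, run_dir / "de_transition.tsv")
    _write_json({"transition": [str(t_a), str(t_b)]},
                run_dir / "de_transition_meta.json")
    return {"n_de": int(len(res.selected)), "n_up": int(len(res.up)),
            "n_down": int(len(res.down)), "transition": [str(t_a), str(t_b)]}


def _stage_refine(config: PipelineConfig, run_dir: Path) -> dict:
    _require(run_dir, "de_transition.tsv", "de_transition_meta.json",
             "timecourse_condition_means.tsv")
    de = pd.read_csv(run_dir / "de_transition.tsv", sep="\t", index_col=0)
    meta_json = json.loads((run_dir / "de_transition_meta.json").read_text())
    t_a, t_b = meta_json["transition"]
    means = io.read_table(run_dir / "timecourse_condition_means.tsv")
    relmat = io.relative_expression(
        io.ExpressionMatrix(means, "percentile75")).values
    genes = [g for g in de.index if g in relmat.index]
    sub = relmat.loc[genes]
    if len(sub):
        tree = timecourse.hclust_genes(sub, distance="uncentered",
                                       linkage="centroid")
        n_cut = min(config.refine_n_cut, len(sub))
        up, down = timecourse.refine_de_by_cluster(tree, sub, (t_a, t_b),
                                                   n_cut=n_cut)
    else:
        up, down = pd.Index([]), pd.Index([])
    _write_tsv(pd.DataFrame({"gene_id": up}), run_dir / "refined_up.tsv",
               index=False)
    _write_tsv(pd.DataFrame({"gene_id": down}), run_dir / "refined_down.tsv",
               index=False)
    return {"n_input": int(len(genes)), "n_up": int(len(up)),
            "n_down": int(len(down))}


def _stage_spike(config: PipelineConfig, run_dir: Path) -> dict:
    _require(run_dir, "timecourse_raw.tsv", "timecourse_metadata.tsv")
    _, means, _ = _timecourse_means(config, run_dir)
    report = timecourse.detect_transient_spike(
        means, min_ratio=config.spike_min_ratio)
    rows = [(str(tp), g) for tp, genes in report.flagged.items() for g in genes]
    _write_tsv(pd.DataFrame(rows, columns=["timepoint", "gene_id"]),
               run_dir / "spike_report.tsv", index=False)
    return {"n_flagged": int(len(report.all_flagged)),
            "modal_timepoint": str(report.modal_timepoint)}


def _stage_fertile_sterile(config: PipelineConfig, run_dir: Path) -> dict:
    _require(run_dir, "fs_raw.tsv", "fs_metadata.tsv")
    raw = _load_raw(run_dir, "fs_raw.tsv")
    meta = _load_meta(run_dir, "fs_metadata.tsv")
    keep = io.filter_by_raw_intensity(raw, threshold=config.raw_min)
    log2 = io.percentile_normalize(io.RawMatrix(raw.values.loc[keep]))
    summary = {}
    for week in sorted(meta.table["week"].unique()):
        res = differential.fertile_sterile_contrast(
            log2.values, meta, week=int(week), fdr_max=config.fdr,
            fc_min=config.fc_fertile_sterile)
        table = res.table.loc[res.selected]
        table.index.name = "gene_id"
        _write_tsv(table, run_dir / f"fs_week{week}.tsv")
        summary[f"week{week}"] = int(len(res.selected))
    return summary


def _stage_enrich(config: PipelineConfig, run_dir: Path) -> dict:
    _require(run_dir, "gene2go.tsv", "slim_mapping.tsv", "go_sets.json")
    gene2go = enrichment.read_gene2go(run_dir / "gene2go.tsv")
    slim = enrichment.read_slim_mapping(run_dir / "slim_mapping.tsv")
    sets = json.loads((run_dir / "go_sets.json").read_text())
    terms = enrichment.map_to_slim(gene2go, slim)
    result = enrichment.hypergeom_enrich(sets["study"], sets["background"],
                                         terms)
    _write_tsv(result, run_dir / "go_enrichment.tsv", index=False)
    top = result.iloc[0] if len(result) else None
    return {"n_terms_tested": int(len(result)),
            "top_term": None if top is None else str(top["term_id"]),
            "top_q": None if top is None else float(top["q"])}


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _stage_motif(config: PipelineConfig, run_dir: Path) -> dict:
    _require(run_dir, "upstream_study.fasta", "upstream_background.fasta")
    study = _read_fasta(run_dir / "upstream_study.fasta")
    background = _read_fasta(run_dir / "upstream_background.fasta")
    res = enrichment.motif_enrichment(study, background, config.motif,
                                      flank=config.flank)
    counts = res.counts.to_frame("matches")
    counts.index.name = "gene_id"
    _write_tsv(counts, run_dir / "motif_counts.tsv")
    _write_json({"pattern": config.motif, "p": res.p,
                 "table": list(map(list, res.table))},
                run_dir / "motif_enrichment.json")
    return {"p": res.p, "study_present": res.study_present}


def _stage_profile(config: PipelineConfig, run_dir: Path) -> dict:
    """Trajectory of the spike (contamination) gene set over the series."""
    _require(run_dir, "spike_report.tsv", "timecourse_condition_means.tsv")
    spikes = pd.read_csv(run_dir / "spike_report.tsv", sep="\t")
    means = io.read_table(run_dir / "timecourse_condition_means.tsv")
    relmat = io.relative_expression(
        io.ExpressionMatrix(means, "percentile75")).values
    genes = spikes["gene_id"].unique().tolist()
    if not genes:
        return {"n_genes": 0}
    profile = enrichment.geneset_profile(relmat, genes)
    profile.index.name = "timepoint"
    _write_tsv(profile, run_dir / "spike_profile.tsv")
    return {"n_genes": len(genes),
            "peak_timepoint": str(profile["mean"].idxmax())}


STAGES: dict[str, Callable[[PipelineConfig, Path], dict]] = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "specificity": _stage_specificity,
    "diurnal": _stage_diurnal,
    "stagewise": _stage_stagewise,
    "anova": _stage_anova,
    "phases": _stage_phases,
    "de": _stage_de,
    "refine": _stage_refine,
    "spike": _stage_spike,
    "fertile_sterile": _stage_fertile_sterile,
    "enrich": _stage_enrich,
    "motif": _stage_motif,
    "profile": _stage_profile,
}


def run_stage(stage: str, config: PipelineConfig, run_dir: str | Path) -> dict:
    """Run one named stage in ``run_dir``; returns its summary metrics.

    A ``<stage>.manifest.json`` with parameter values and output
    checksums is written next to the outputs.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(STAGES)}")
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    before = {p for p in run_dir.iterdir() if p.is_file()}
    logger.info("running stage %s in %s", stage, run_dir)
    summary = STAGES[stage](config, run_dir)
    after = {p for p in run_dir.iterdir()
             if p.is_file() and not p.name.endswith(".manifest.json")}
    outputs = sorted(after - before) or sorted(after)
    _manifest(stage, config, run_dir, inputs=[], outputs=outputs)
    return summary
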