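"""Synthetic field-transcriptome generator with known ground truth.

Emulates the study design end to end so every pipeline stage is
testable without the original arrays:

* a 48-condition organ/tissue panel (leaf blade, leaf sheath, root and
  stem sampled day/night across stages; inflorescence, anther, pistil,
  lemma/palea by size; ovary, embryo and endosperm by days after
  flowering) with 3 replicates per condition (one anther stage has 2),
  and planted organ-specific, diurnal, stage-transition and
  lemma/palea-effect genes;
* a 17-timepoint weekly leaf series (13-125 days after transplanting)
  with two planted transcriptome shifts and a one-timepoint pollen-
  contamination spike at flowering;
* a fertile vs sterile flag-leaf series with attenuated late-phase
  change in the sterile lines;
* upstream promoter sequences with a planted degenerate-motif
  enrichment, and a GO annotation fixture with one planted term.

Effects are planted on the log2 scale; export multiplies by a
per-sample log-normal scale factor and returns linear "raw" intensity
so the pipeline's own normalization is exercised.  Every generator is
deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import IUPAC_CODES, MotifPattern
from .io import RawMatrix, SampleMetadata

__all__ = [
    "field_conditions",
    "FieldConfig",
    "generate_field_transcriptome",
    "TimecourseConfig",
    "generate_timecourse",
    "FertileSterileConfig",
    "generate_fertile_sterile",
    "generate_upstreams",
    "generate_go_fixture",
]


def field_conditions() -> pd.DataFrame:
    """The 48-condition organ/tissue design table.

    Columns: condition_id, organ, dat, time_of_day, stage, replicates.
    Vegetative organs carry DAT and time of day; floral organs carry a
    size/stage index; seed tissues carry days after flowering encoded in
    the stage column.  143 arrays in total (one anther condition has
    two replicates).
    """
    rows: list[tuple] = []

    def veg(prefix: str, organ: str, dats: list[int]):
        i = 0
        for dat in dats:
            for tod in ("12:00", "24:00"):
                i += 1
                stage = {0: "vegetative", 1: "reproductive", 2: "ripening"}[
                    dats.index(dat)]
                rows.append((f"{prefix}{i}", organ, dat, tod, stage, 3))

    veg("LB", "leaf blade", [27, 76, 125])
    veg("LS", "leaf sheath", [27, 76])
    veg("RO", "root", [27, 76])
    veg("ST", "stem", [83, 90])
    for i in range(1, 4):
        rows.append((f"IN{i}", "inflorescence", None, None, f"size{i}", 3))
    for i in range(1, 5):
        rows.append((f"AN{i}", "anther", None, None, f"size{i}", 2 if i == 1 else 3))
    for i in range(1, 4):
        rows.append((f"PI{i}", "pistil", None, None, f"size{i}", 3))
    for i in range(1, 4):
        rows.append((f"LE{i}", "lemma", None, None, f"size{i}", 3))
        rows.append((f"PA{i}", "palea", None, None, f"size{i}", 3))
    for i in range(1, 5):
        rows.append((f"OV{i}", "ovary", None, None, f"daf{i}", 3))
    for i in range(1, 6):
        rows.append((f"EM{i}", "embryo", None, None, f"daf{i}", 3))
    for i in range(1, 6):
        rows.append((f"EN{i}", "endosperm", None, None, f"daf{i}", 3))
    df = pd.DataFrame(
        rows, columns=["condition_id", "organ", "dat", "time_of_day",
                       "stage", "replicates"],
    )
    assert len(df) == 48 and int(df["replicates"].sum()) == 143
    return df


@dataclass(frozen=True)
class FieldConfig:
    """Study conditions of the organ/tissue panel generator."""

    n_genes: int = 5000
    seed: int = 1
    noise_sd: float = 0.25          # replicate noise, log2 units
    baseline_mean: float = 8.0      # per-gene baseline, log2 units
    baseline_sd: float = 2.0
    scale_sd: float = 0.3           # per-sample scale shift, log2 units
    n_specific: int = 50
    specific_effect: float = 10.0   # log2 units in the target condition
    diurnal_frac_leaf_blade: float = 0.07
    n_diurnal_leaf_sheath: int = 70
    diurnal_amplitude: float = 2.0  # peak-to-trough, log2 units
    n_stage_universal: int = 215    # change in leaf blade + sheath + root
    n_stage_single: int = 50        # per-tissue-only stage genes
    stage_effect: float = 2.0
    n_lemma_palea_tissue: int = 23
    n_lemma_palea_stage: int = 150
    lemma_palea_effect: float = 1.5
    n_silent: int = 3500            # genes silent in a random condition subset
    silent_prob: float = 0.3        # per-context silence probability
    silent_depth: float = 10.0      # log2 drop below baseline when silent
    silent_max_fraction: float = 0.4  # cap on silent contexts per gene, so
    #   background genes stay broadly expressed (entropy above the
    #   specificity cutoff); only planted specific genes are designed
    #   to concentrate their expression

    def __post_init__(self) -> None:
        planted = (self.n_specific
                   + int(round(self.diurnal_frac_leaf_blade * self.n_genes))
                   + self.n_diurnal_leaf_sheath
                   + self.n_stage_universal + 3 * self.n_stage_single
                   + self.n_lemma_palea_tissue + self.n_lemma_palea_stage
                   + self.n_silent)
        if planted > self.n_genes:
            raise ValueError(
                f"planted gene count ({planted}) exceeds n_genes ({self.n_genes})")

    @classmethod
    def scaled(cls, n_genes: int, seed: int = 1, **overrides) -> "FieldConfig":
        """Default design rescaled to ``n_genes`` (planted counts scale
        proportionally; effect sizes and rates are unchanged)."""
        base = cls()
        factor = n_genes / base.n_genes
        counts = {f: max(1, int(round(getattr(base, f) * factor)))
                  for f in ("n_specific", "n_diurnal_leaf_sheath",
                            "n_stage_universal", "n_stage_single",
                            "n_lemma_palea_tissue", "n_lemma_palea_stage",
                            "n_silent")}
        counts.update(overrides)
        return cls(n_genes=n_genes, seed=seed, **counts)


def _gene_ids(n: int) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(n)], name="probe_id")


def _export_raw(log2_matrix: np.ndarray, rng: np.random.Generator,
                scale_sd: float) -> np.ndarray:
    shift = rng.normal(0.0, scale_sd, size=log2_matrix.shape[1])
    return np.exp2(log2_matrix + shift[None, :])


def generate_field_transcriptome(
    config: FieldConfig = FieldConfig(),
) -> tuple[RawMatrix, SampleMetadata, dict]:
    """Raw matrix + metadata + truth tables for the organ/tissue panel."""
    rng = np.random.default_rng(config.seed)
    cond = field_conditions()
    sample_rows = []
    for _, c in cond.iterrows():
        for r in range(1, int(c.replicates) + 1):
            sample_rows.append((f"{c.condition_id}_r{r}", c.condition_id,
                                c.organ, c.dat, c.time_of_day, c.stage, r))
    meta = pd.DataFrame(
        sample_rows, columns=["sample_id", "condition_id", "organ", "dat",
                              "time_of_day", "stage", "replicate"],
    )
    n_samples = len(meta)
    genes = _gene_ids(config.n_genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_genes)
    M = np.tile(baseline[:, None], (1, n_samples))

    col_of = {s: j for j, s in enumerate(meta["sample_id"])}

    def cols(mask: pd.Series) -> np.ndarray:
        return np.fromiter(
            (col_of[s] for s in meta.loc[mask, "sample_id"]), dtype=int)

    truth: dict = {"specific": {}, "diurnal": {}, "stage_universal": {},
                   "stage_single": {}, "lemma_palea_tissue": [],
                   "lemma_palea_stage": [], "silent": {}}
    cursor = 0

    # organ/tissue-specific genes, round-robin over the 48 conditions
    cond_ids = cond["condition_id"].tolist()
    for i in range(config.n_specific):
        g = cursor + i
        target = cond_ids[i % len(cond_ids)]
        M[g, cols(meta["condition_id"] == target)] += config.specific_effect
        truth["specific"][str(genes[g])] = target
    cursor += config.n_specific

    # diurnal genes (half peak at day, half at night)
    def plant_diurnal(organ: str, count: int):
        nonlocal cursor
        day = cols((meta["organ"] == organ) & (meta["time_of_day"] == "12:00"))
        night = cols((meta["organ"] == organ) & (meta["time_of_day"] == "24:00"))
        half = config.diurnal_amplitude / 2.0
        for i in range(count):
            g = cursor + i
            peak = "day" if i % 2 == 0 else "night"
            hi, lo = (day, night) if peak == "day" else (night, day)
            M[g, hi] += half
            M[g, lo] -= half
            truth["diurnal"][str(genes[g])] = {"organ": organ, "peak": peak}
        cursor += count

    plant_diurnal("leaf blade",
                  int(round(config.diurnal_frac_leaf_blade * config.n_genes)))
    plant_diurnal("leaf sheath", config.n_diurnal_leaf_sheath)

    # stage-transition genes: vegetative -> reproductive shift
    stage_tissues = ["leaf blade", "leaf sheath", "root"]

    def plant_stage(tissues: list[str], count: int, record: str):
        nonlocal cursor
        for i in range(count):
            g = cursor + i
            sign = 1.0 if rng.random() < 0.5 else -1.0
            for organ in tissues:
                later = cols((meta["organ"] == organ)
                             & (meta["stage"] != "vegetative"))
                M[g, later] += sign * config.stage_effect
            key = str(genes[g])
            if record == "universal":
                truth["stage_universal"][key] = "up" if sign > 0 else "down"
            else:
                truth["stage_single"][key] = tissues[0]
        cursor += count

    plant_stage(stage_tissues, config.n_stage_universal, "universal")
    for organ in stage_tissues:
        plant_stage([organ], config.n_stage_single, "single")

    # lemma/palea effects for the two-way ANOVA
    lemma = cols(meta["organ"] == "lemma")
    palea = cols(meta["organ"] == "palea")
    for i in range(config.n_lemma_palea_tissue):
        g = cursor + i
        sign = 1.0 if rng.random() < 0.5 else -1.0
        M[g, lemma] += sign * config.lemma_palea_effect
        truth["lemma_palea_tissue"].append(str(genes[g]))
    cursor += config.n_lemma_palea_tissue
    lp = meta["organ"].isin(["lemma", "palea"])
    for i in range(config.n_lemma_palea_stage):
        g = cursor + i
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for k, size in enumerate(["size1", "size2", "size3"]):
            offset = sign * config.lemma_palea_effect * (k - 1)
            M[g, cols(lp & (meta["stage"] == size))] += offset
        truth["lemma_palea_stage"].append(str(genes[g]))
    cursor += config.n_lemma_palea_stage

    # silent genes: strongly repressed in a random subset of biological
    # contexts (organ x stage; day/night pairs share their context), so
    # per-condition 'expressed' fractions fall below 1 by design without
    # creating spurious diurnal contrasts
    context = cond[["condition_id", "organ", "stage"]].copy()
    context["ctx"] = context["organ"] + "|" + context["stage"].astype(str)
    ctx_ids = context["ctx"].unique().tolist()
    conds_of_ctx = {
        ctx: context.loc[context["ctx"] == ctx, "condition_id"].tolist()
        for ctx in ctx_ids
    }
    ctx_cap = int(config.silent_max_fraction * len(ctx_ids))
    for i in range(config.n_silent):
        g = cursor + i
        k = min(int(rng.binomial(len(ctx_ids), config.silent_prob)), ctx_cap)
        chosen = rng.choice(len(ctx_ids), size=k, replace=False)
        silent_conds = [cid for j in chosen
                        for cid in conds_of_ctx[ctx_ids[j]]]
        for cid in silent_conds:
            M[g, cols(meta["condition_id"] == cid)] -= config.silent_depth
        truth["silent"][str(genes[g])] = silent_conds
    cursor += config.n_silent

    M += rng.normal(0.0, config.noise_sd, size=M.shape)
    raw = _export_raw(M, rng, config.scale_sd)
    values = pd.DataFrame(raw, index=genes, columns=meta["sample_id"].tolist())
    return RawMatrix(values), SampleMetadata(meta), truth


@dataclass(frozen=True)
class TimecourseConfig:
    """Study conditions of the weekly leaf-series generator."""

    n_genes: int = 5000
    seed: int = 1
    n_timepoints: int = 17
    replicates: int = 3
    dat_start: int = 13
    dat_step: int = 7
    boundaries: tuple[int, ...] = (5, 12)  # 1-based timepoint after which a shift occurs
    n_shift_per_boundary: int = 400
    shift_range: tuple[float, float] = (1.0, 3.0)  # |step|, log2 units
    n_spike: int = 80
    spike_timepoint: int = 12          # 1-based (90 DAT at weekly sampling)
    spike_ratio: float = 100.0         # linear fold elevation of the spike
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    scale_sd: float = 0.3

    def __post_init__(self) -> None:
        if not all(1 <= b <= self.n_timepoints - 1 for b in self.boundaries):
            raise ValueError("boundaries must lie within 1..n_timepoints-1")
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must be strictly increasing")
        planted = len(self.boundaries) * self.n_shift_per_boundary + self.n_spike
        if planted > self.n_genes:
            raise ValueError("planted gene count exceeds n_genes")

    @classmethod
    def scaled(cls, n_genes: int, seed: int = 1, **overrides) -> "TimecourseConfig":
        """Default design rescaled to ``n_genes``."""
        base = cls()
        factor = n_genes / base.n_genes
        counts = {f: max(1, int(round(getattr(base, f) * factor)))
                  for f in ("n_shift_per_boundary", "n_spike")}
        counts.update(overrides)
        return cls(n_genes=n_genes, seed=seed, **counts)

    @property
    def dat_labels(self) -> list[int]:
        return [self.dat_start + self.dat_step * k
                for k in range(self.n_timepoints)]


def generate_timecourse(
    config: TimecourseConfig = TimecourseConfig(),
) -> tuple[RawMatrix, SampleMetadata, dict]:
    """Raw matrix + metadata + truth for the weekly leaf time course."""
    rng = np.random.default_rng(config.seed)
    dats = config.dat_labels
    sample_rows = [
        (f"T{dat}_r{r}", f"T{dat}", "leaf blade", dat, "12:00", r)
        for dat in dats for r in range(1, config.replicates + 1)
    ]
    meta = pd.DataFrame(sample_rows, columns=[
        "sample_id", "condition_id", "organ", "dat", "time_of_day", "replicate"])
    genes = _gene_ids(config.n_genes)
    n_samples = len(meta)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_genes)
    M = np.tile(baseline[:, None], (1, n_samples))
    tp_of_sample = np.repeat(np.arange(config.n_timepoints), config.replicates)

    truth: dict = {"shift": {}, "spike": [],
                   "boundaries": list(config.boundaries),
                   "spike_timepoint_dat": dats[config.spike_timepoint - 1]}
    cursor = 0
    lo, hi = config.shift_range
    for b in config.boundaries:
        after = tp_of_sample >= b  # 0-based tp index b == first tp after boundary
        for i in range(config.n_shift_per_boundary):
            g = cursor + i
            step = rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0)
            M[g, after] += step
            truth["shift"][str(genes[g])] = {"boundary": b, "step": step}
        cursor += config.n_shift_per_boundary
    spike_cols = tp_of_sample == (config.spike_timepoint - 1)
    for i in range(config.n_spike):
        g = cursor + i
        M[g, spike_cols] += np.log2(config.spike_ratio)
        truth["spike"].append(str(genes[g]))
    cursor += config.n_spike

    M += rng.normal(0.0, config.noise_sd, size=M.shape)
    raw = _export_raw(M, rng, config.scale_sd)
    values = pd.DataFrame(raw, index=genes, columns=meta["sample_id"].tolist())
    return RawMatrix(values), SampleMetadata(meta), truth


@dataclass(frozen=True)
class FertileSterileConfig:
    """Study conditions of the fertile/sterile flag-leaf generator.

    Senescence-associated genes change after heading in fertile plants;
    the same change is attenuated in the seedless (sterile) lines, so
    the fertile-sterile divergence grows with week after heading.
    """

    n_genes: int = 5000
    seed: int = 1
    weeks: tuple[int, ...] = (0, 1, 2, 3)
    replicates: int = 3               # the three sterile lines / their sibs
    n_senescence: int = 300
    effect_range: tuple[float, float] = (2.5, 5.0)  # fertile |effect|, log2
    schedule: tuple[float, ...] = (0.0, 0.6, 0.85, 1.0)  # per-week fraction
    attenuation: float = 0.25         # sterile effect = attenuation * fertile
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    scale_sd: float = 0.3

    def __post_init__(self) -> None:
        if len(self.schedule) != len(self.weeks):
            raise ValueError("schedule must give one fraction per week")
        if self.n_senescence > self.n_genes:
            raise ValueError("planted gene count exceeds n_genes")

    @classmethod
    def scaled(cls, n_genes: int, seed: int = 1, **overrides) -> "FertileSterileConfig":
        """Default design rescaled to ``n_genes``."""
        base = cls()
        n_sen = max(1, int(round(base.n_senescence * n_genes / base.n_genes)))
        kwargs = {"n_senescence": n_sen}
        kwargs.update(overrides)
        return cls(n_genes=n_genes, seed=seed, **kwargs)


def generate_fertile_sterile(
    config: FertileSterileConfig = FertileSterileConfig(),
) -> tuple[RawMatrix, SampleMetadata, dict]:
    """Raw matrix + metadata + truth for the fertile vs sterile series."""
    rng = np.random.default_rng(config.seed)
    sample_rows = []
    for w, frac in zip(config.weeks, config.schedule):
        for geno in ("fertile", "sterile"):
            for r in range(1, config.replicates + 1):
                sample_rows.append((f"{geno[0].upper()}W{w}_r{r}",
                                    f"{geno[0].upper()}W{w}", "flag leaf",
                                    geno, w, r))
    meta = pd.DataFrame(sample_rows, columns=[
        "sample_id", "condition_id", "organ", "genotype", "week", "replicate"])
    genes = _gene_ids(config.n_genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_genes)
    M = np.tile(baseline[:, None], (1, len(meta)))
    week_arr = meta["week"].to_numpy()
    geno_arr = meta["genotype"].to_numpy()
    frac_of_week = dict(zip(config.weeks, config.schedule))

    truth: dict = {"senescence": {}}
    lo, hi = config.effect_range
    for i in range(config.n_senescence):
        e = rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0)
        for j in range(len(meta)):
            frac = frac_of_week[week_arr[j]]
            mult = 1.0 if geno_arr[j] == "fertile" else config.attenuation
            M[i, j] += e * frac * mult
        truth["senescence"][str(genes[i])] = e

    M += rng.normal(0.0, config.noise_sd, size=M.shape)
    raw = _export_raw(M, rng, config.scale_sd)
    values = pd.DataFrame(raw, index=genes, columns=meta["sample_id"].tolist())
    return RawMatrix(values), SampleMetadata(meta), truth


def _concrete_motif(pattern: MotifPattern, rng: np.random.Generator) -> str:
    out = []
    for code in pattern.iupac:
        choices = sorted(IUPAC_CODES[code] - {"N"}) or ["A", "C", "G", "T"]
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def generate_upstreams(
    n_study: int,
    n_background: int,
    length: int = 1000,
    study_rate: float = 0.6,
    background_rate: float = 0.2,
    pattern: MotifPattern | str = "GNATATNC",
    seed: int = 1,
) -> tuple[dict[str, str], list[str], dict]:
    """Upstream sequences with a planted motif enrichment.

    Returns (sequences for the whole universe, study gene ids, truth).
    The study set is the first ``n_study`` ids of the universe; a random
    concrete expansion of the IUPAC pattern is inserted at a random
    position in the designated fraction of study / remaining background
    sequences.  Truth records insertion positions.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    if length < pattern.length:
        raise ValueError("sequence length shorter than the pattern")
    for rate in (study_rate, background_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    total = n_study + n_background
    ids = [f"G{i:05d}" for i in range(total)]
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    truth: dict = {"inserted": {}}
    for i, gid in enumerate(ids):
        seq = list(bases[rng.integers(0, 4, size=length)])
        rate = study_rate if i < n_study else background_rate
        if rng.random() < rate:
            pos = int(rng.integers(0, length - pattern.length + 1))
            seq[pos : pos + pattern.length] = _concrete_motif(pattern, rng)
            truth["inserted"][gid] = pos
        sequences[gid] = "".join(seq)
    return sequences, ids[:n_study], truth


def generate_go_fixture(
    n_genes: int = 2000,
    n_terms: int = 50,
    seed: int = 1,
    study_size: int = 100,
    planted: bool = True,
    enriched_fraction: float = 0.6,
    generics_per_slim: int = 3,
    annotations_per_gene: int = 3,
) -> dict:
    """Random gene->GO annotations with one optionally planted slim term.

    Returns a dict with ``gene2go`` and ``slim_mapping`` frames, the
    ``study`` gene list, the ``background`` list and ``truth`` naming
    the enriched slim term (or None).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    slims = [f"SLIM:{i:04d}" for i in range(n_terms)]
    generics = [f"GO:{i:06d}" for i in range(n_terms * generics_per_slim)]
    slim_mapping = pd.DataFrame({
        "term_id": generics,
        "slim_id": [slims[i // generics_per_slim] for i in range(len(generics))],
    })
    rows = []
    for g in genes:
        for t in rng.choice(len(generics), size=annotations_per_gene,
                            replace=False):
            rows.append((g, generics[t]))
    study = [genes[i] for i in rng.choice(n_genes, size=study_size,
                                          replace=False)]
    truth: dict = {"enriched_term": None}
    if planted:
        enriched_slim = slims[0]
        pool = [t for t, s in zip(slim_mapping["term_id"],
                                  slim_mapping["slim_id"]) if s == enriched_slim]
        for g in study:
            if rng.random() < enriched_fraction:
                rows.append((g, pool[int(rng.integers(len(pool)))]))
        truth["enriched_term"] = enriched_slim
    gene2go = pd.DataFrame(rows, columns=["gene_id", "term_id"]).drop_duplicates()
    return {"gene2go": gene2go, "slim_mapping": slim_mapping,
            "study": study, "background": genes, "truth": truth}
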