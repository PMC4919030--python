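"""End-to-end survey pipeline on synthetic or user data.

Stages (in order): simulate -> seed-collect -> align -> build profile ->
scan -> classify -> architectures -> align single-domain set -> tree ->
aLRT -> collapse -> root -> reports.  A single master seed fans out to
per-stage seeds by a fixed offset scheme, so stages are independently
re-runnable; reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import arch as arch_mod
from . import io as io_mod
from . import msa as msa_mod
from . import phmm as phmm_mod
from . import phylo as phylo_mod
from . import synth as synth_mod
from .ratemodel import lg_model
from .scoring import ScoringScheme

log = logging.getLogger(__name__)

STAGE_SEEDS = {"templates": 0, "simulate": 1, "seed_collect": 2,
               "calibrate": 3, "tree": 4, "bootstrap": 5}


def stage_seed(master: int, stage: str) -> int:
    """Fan a master seed out to an independent per-stage seed.  Spawn keys
    keep the streams disjoint even when the master seed is small."""
    ss = np.random.SeedSequence(entropy=master,
                                spawn_key=(STAGE_SEEDS[stage],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the survey's published settings."""

    out_dir: str = "hrsurvey_out"
    seed: int = 0
    simulate: bool = True
    proteome_fasta: str | None = None
    n_proteins: int = 300
    planting_rate: float = 0.3
    n_shuffles: int = 200
    matrix_name: str = "BLOSUM50"
    gap_open: int = -10
    gap_extend: int = -2
    homolog_expect: float = 1e-3
    seed_expect: float = 1e-5
    reference_coverage: float = 0.95
    protein_coverage: float = 0.85
    anchor_weight: float = 5.0
    hit_expect: float = 1e-3
    calibration_n: int = 300
    n_categories: int = 6
    gamma_shape: float = 1.151
    collapse_support: float = 0.6
    min_orphan: int = 50
    max_tree_tips: int = 12
    sites_divergence: tuple = (0.1, 0.8)

    def validate(self):
        for name, lo, hi in [("planting_rate", 0, 1), ("homolog_expect", 0, 1e6),
                             ("reference_coverage", 0, 1.01),
                             ("protein_coverage", 0, 1.01),
                             ("collapse_support", 0, 1)]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sites_divergence" in data:
            data["sites_divergence"] = tuple(data["sites_divergence"])
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict, t0: float):
        self.stages.append({
            "stage": stage,
            "outputs": {name: io_mod.sha256_file(p) for name, p in outputs.items()},
            "wall_time_s": round(time.time() - t0, 3),
        })

    def write(self, path):
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages,
                       "warnings": self.warnings}, fh, indent=2, sort_keys=True)

    def checksums(self) -> dict:
        out = {}
        for st in self.stages:
            out.update(st["outputs"])
        return out


class StageError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> RunManifest:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(asdict(config))
    scheme = ScoringScheme(config.matrix_name, config.gap_open, config.gap_extend)
    base = config.seed

    def stage(name):
        log.info("pipeline stage: %s", name)
        return time.time()

    # -- simulate ---------------------------------------------------------
    t0 = stage("simulate")
    try:
        hr, hhe, decoys = synth_mod.make_default_templates(
            stage_seed(base, "templates"))
        if config.simulate:
            proteome = synth_mod.generate_proteome(
                [hr, hhe] + decoys, synth_mod.default_architecture_specs(),
                config.n_proteins, config.planting_rate,
                stage_seed(base, "simulate"),
                divergence_range=config.sites_divergence)
            fasta = out / "proteome.fasta"
            truth = out / "truth.tsv"
            proteome.write(fasta, truth)
            db = proteome.proteins
            manifest.record("simulate", {"proteome.fasta": fasta,
                                         "truth.tsv": truth}, t0)
        else:
            fasta = Path(config.proteome_fasta)
            db = io_mod.read_fasta(fasta)
            manifest.record("load", {"proteome.fasta": fasta}, t0)
    except Exception as err:  # noqa: BLE001 - typed re-raise with stage name
        raise StageError("simulate", err) from err

    # -- seed collection + alignment + profile ---------------------------
    t0 = stage("profile")
    try:
        references = [("ref_O2Hr", hr.consensus)]
        seeds = phmm_mod.collect_seed(references, db,
                                      expect_cutoff=config.seed_expect,
                                      coverage_cutoff=config.reference_coverage,
                                      scheme=scheme, n_shuffles=config.n_shuffles,
                                      seed=stage_seed(base, "seed_collect"))
        if len(seeds) < 2:
            seeds = [("consensus", hr.consensus),
                     ("consensus_dup", hr.consensus)] + seeds
            manifest.warnings.append("seed collection found < 2 sequences; "
                                     "profile built from the reference")
        seed_seqs = [(pid, seq[:]) for pid, seq in seeds]
        aln = msa_mod.progressive_align(seed_seqs, scheme)
        aln_path = out / "seed.afa"
        aln.to_fasta(aln_path)
        anchors = _anchor_columns(aln, hr, config.anchor_weight)
        model = phmm_mod.build_phmm(aln, anchors=anchors, profile_id="O2_Hr")
        hmm_path = out / "o2hr.phmm"
        phmm_mod.write_phmm(model, hmm_path)
        manifest.record("profile", {"seed.afa": aln_path,
                                    "o2hr.phmm": hmm_path}, t0)
    except Exception as err:
        raise StageError("profile", err) from err

    # -- scan + classify --------------------------------------------------
    t0 = stage("scan")
    try:
        calib = phmm_mod.calibrate_evalue(model, n_random=config.calibration_n,
                                          length=200,
                                          seed=stage_seed(base, "calibrate"))
        hits = []
        for pid, seq in db:
            found = phmm_mod.viterbi_scan(model, seq, pid, floor=0.0,
                                          multihit=True)
            for h in found:
                h.evalue = calib.evalue(h.bit_score, len(db))
                if h.evalue < config.hit_expect:
                    h.classification = phmm_mod.classify_coverage(
                        h, config.protein_coverage)
                    hits.append(h)
        hits_path = out / "hits.tsv"
        io_mod.write_hits_tsv(hits_path, hits)
        manifest.record("scan", {"hits.tsv": hits_path}, t0)
    except Exception as err:
        raise StageError("scan", err) from err

    # -- architectures ----------------------------------------------------
    t0 = stage("architect")
    try:
        by_protein: dict = {}
        for h in hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        annotations = [arch_mod.resolve_overlaps(v, min_orphan=config.min_orphan)
                       for v in by_protein.values()]
        species_map = {pid: "synth" for pid, _ in db}
        arch_path = out / "architectures.tsv"
        import pandas as pd
        rows = []
        focal_annotations = []
        for ann in annotations:
            s = arch_mod.architecture_string(ann, "O2_Hr")
            rows.append({"protein_id": ann.protein_id, "architecture": str(s),
                         "terminus_class": s.terminus_class})
            if any(h.profile_id == "O2_Hr" for h in ann.accepted):
                focal_annotations.append(ann)
        pd.DataFrame(rows, columns=["protein_id", "architecture",
                                    "terminus_class"]).to_csv(
            arch_path, sep="\t", index=False)
        outputs = {"architectures.tsv": arch_path}
        if focal_annotations:
            cat = arch_mod.catalog(focal_annotations, species_map)
            copies = arch_mod.copy_number_table(focal_annotations, species_map)
            copies_path = out / "copies.tsv"
            copies.to_csv(copies_path, sep="\t", index=False)
            pa = arch_mod.presence_absence(cat, sorted({s for ss in
                                                        cat.species.values()
                                                        for s in ss}))
            pa_path = out / "presence_absence.tsv"
            pa.to_csv(pa_path, sep="\t")
            outputs.update({"copies.tsv": copies_path,
                            "presence_absence.tsv": pa_path})
        manifest.record("architect", outputs, t0)
    except Exception as err:
        raise StageError("architect", err) from err

    # -- phylogeny of the single-domain set -------------------------------
    t0 = stage("tree")
    try:
        single = [(h.protein_id, db_seq)
                  for h in hits if h.classification == "single_domain"
                  for pid2, db_seq in db if pid2 == h.protein_id]
        tree_outputs = {}
        if len(single) >= 4:
            single = single[:config.max_tree_tips]
            aln2 = msa_mod.progressive_align(single, scheme)
            model_ph = lg_model(config.gamma_shape, config.n_categories)
            tree, ll = phylo_mod.ml_tree(aln2, model_ph)
            tree = phylo_mod.alrt_support(tree, aln2, model_ph)
            tree = phylo_mod.collapse_low_support(tree, config.collapse_support)
            tree = phylo_mod.midpoint_root(tree)
            tree_path = out / "tree.nwk"
            tree.write(tree_path)
            tree_outputs["tree.nwk"] = tree_path
        else:
            manifest.warnings.append("fewer than 4 single-domain hits; "
                                     "tree stage skipped")
        manifest.record("tree", tree_outputs, t0)
    except Exception as err:
        raise StageError("tree", err) from err

    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)
    return manifest


def _anchor_columns(aln, template, weight: float) -> list:
    """Map template anchor positions to alignment columns via the first seed
    row that is an (ungapped) template homolog of equal length."""
    anchors = []
    row = aln.rows[0][1]
    residue_to_col = {}
    r = 0
    for col, ch in enumerate(row):
        if ch != "-":
            residue_to_col[r] = col
            r += 1
    if r != template.length:
        return []
    for pos, res in template.anchor_positions:
        anchors.append((residue_to_col[pos], res, weight))
    return anchors
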