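"""Formats, configuration, and end-to-end orchestration.

A single YAML configuration drives both analysis arms — the genetic arm
(filtering → allele-frequency MCMC → {PCA, G_ST → NMDS, diversity} and
pseudo-haploid sampling → admixture over K → ΔK) and the phenotype arm
(GPA → allometry → {PCA + ANOVA/Tukey, CVA, Procrustes distances,
ellipses}; melanization → size correction → ANOVA/Tukey).  Either arm runs
independently when only its inputs are present.  Inputs may be files
(read-count TSV, minimal VCF with AD fields, landmark CSV/TPS,
melanization CSV) or synthetic-generation blocks.

All randomness funnels through named per-stage seeds derived from the one
configured seed, so identical configurations produce bytewise-identical
tables.
"""

from __future__ import annotations

import copy
import json
import logging
import os
import zlib
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import admixture as admix
from . import genomod, melan_stats, morpho, popstruct, synthdata
from .genomod import ReadCountMatrix
from .morpho import LandmarkSet

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunReport",
    "load_config",
    "load_inputs",
    "run_full_pipeline",
    "write_report",
    "stage_seed",
    "read_read_counts_tsv",
    "write_read_counts_tsv",
    "read_vcf",
    "write_vcf",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_tps",
    "write_tps",
]

PAPER_SCALE_FREQUENCY = {"steps": 100_000, "burnin": 10_000}
PAPER_SCALE_ADMIXTURE = {"steps": 100_000, "burnin": 50_000}

_DEFAULTS: dict = {
    "seed": 0,
    "outdir": "flightdiff_out",
    "genetic": {
        "filter": {},
        "mcmc": {"err": 0.005, "steps": 10_000, "burnin": 2_000, "thin": 10},
        "admixture": {
            "k_min": 1, "k_max": 4, "replicates": 3,
            "steps": 10_000, "burnin": 5_000, "thin": 10, "alpha": 1.0,
        },
        "nmds": {"dims": 3, "restarts": 8},
        "paper_scale": False,
    },
    "morpho": {"tangent_projection": False, "permutations": 10_000,
               "reflect_side": None},
    "melanization": {"threshold": "isodata"},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Validated configuration with defaults merged in."""

    raw: dict

    def __post_init__(self) -> None:
        self.raw = copy.deepcopy(_merge(_DEFAULTS, self.raw or {}))
        if self.genetic.get("paper_scale"):
            self.genetic["mcmc"] = _merge(self.genetic["mcmc"], PAPER_SCALE_FREQUENCY)
            self.genetic["admixture"] = _merge(
                self.genetic["admixture"], PAPER_SCALE_ADMIXTURE
            )
        for section, keys in (
            ("genetic", ("read_counts", "vcf", "popmap")),
            ("morpho", ("landmarks_csv", "tps", "group_map")),
            ("melanization", ("table",)),
        ):
            for key in keys:
                path = self.raw.get(section, {}).get(key)
                if path and not os.path.exists(path):
                    raise FileNotFoundError(f"{section}.{key}: {path} does not exist")

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def outdir(self) -> str:
        return self.raw["outdir"]

    @property
    def genetic(self) -> dict:
        return self.raw.get("genetic", {})

    @property
    def morpho(self) -> dict:
        return self.raw.get("morpho", {})

    @property
    def melanization(self) -> dict:
        return self.raw.get("melanization", {})

    def has_genetic_input(self) -> bool:
        g = self.genetic
        return any(k in g for k in ("synthetic", "read_counts", "vcf"))

    def has_morpho_input(self) -> bool:
        m = self.morpho
        return any(k in m for k in ("synthetic", "landmarks_csv", "tps"))

    def has_melanization_input(self) -> bool:
        m = self.melanization
        return any(k in m for k in ("synthetic", "table"))


def load_config(path_or_dict) -> PipelineConfig:
    if isinstance(path_or_dict, PipelineConfig):
        return path_or_dict
    if isinstance(path_or_dict, dict):
        return PipelineConfig(raw=path_or_dict)
    with open(path_or_dict) as fh:
        return PipelineConfig(raw=yaml.safe_load(fh) or {})


def stage_seed(seed: int, name: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from one root seed."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunReport:
    """Provenance, produced tables, and warnings from one pipeline run."""

    provenance: dict
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    files: list = field(default_factory=list)

    def add(self, name: str, frame: pd.DataFrame, operation: str, **params) -> None:
        frame = frame.copy()
        frame.attrs["operation"] = operation
        frame.attrs["params"] = params
        self.tables[name] = frame


# ---------------------------------------------------------------------------
# readers / writers

def write_read_counts_tsv(rcm: ReadCountMatrix, path: str) -> None:
    """Long-format TSV: locus_id, ind_id, pop, ref_count, alt_count."""
    n, L = rcm.ref.shape
    frame = pd.DataFrame(
        {
            "locus_id": np.tile(rcm.loci, n),
            "ind_id": np.repeat(rcm.individuals, L),
            "pop": np.repeat(rcm.populations, L),
            "ref_count": rcm.ref.ravel(),
            "alt_count": rcm.alt.ravel(),
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_read_counts_tsv(path: str) -> ReadCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "ind_id": str, "pop": str})
    required = {"locus_id", "ind_id", "pop", "ref_count", "alt_count"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    loci = list(dict.fromkeys(df["locus_id"]))
    inds = list(dict.fromkeys(df["ind_id"]))
    li = {l: j for j, l in enumerate(loci)}
    ii = {s: i for i, s in enumerate(inds)}
    ref = np.zeros((len(inds), len(loci)), dtype=np.int32)
    alt = np.zeros_like(ref)
    pops = {}
    rows = df["ind_id"].map(ii).to_numpy()
    cols = df["locus_id"].map(li).to_numpy()
    ref[rows, cols] = df["ref_count"].to_numpy()
    alt[rows, cols] = df["alt_count"].to_numpy()
    for s, p in zip(df["ind_id"], df["pop"]):
        prev = pops.setdefault(s, p)
        if prev != p:
            raise ValueError(f"{path}: individual {s} has conflicting populations")
    return ReadCountMatrix(
        loci=np.array(loci, dtype=object),
        individuals=np.array(inds, dtype=object),
        populations=np.array([pops[s] for s in inds], dtype=object),
        ref=ref,
        alt=alt,
    )


def write_vcf(rcm: ReadCountMatrix, path: str) -> None:
    """Minimal single-contig VCF with per-sample AD (ref,alt) fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write("##contig=<ID=chr1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in rcm.individuals)
            + "\n"
        )
        for j, locus in enumerate(rcm.loci):
            cells = [
                f"./.:{rcm.ref[i, j]},{rcm.alt[i, j]}"
                for i in range(rcm.n_individuals)
            ]
            fh.write(
                f"chr1\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT:AD\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path: str, popmap) -> ReadCountMatrix:
    """Read a VCF with AD fields; ``popmap`` maps sample -> population.

    ``popmap`` may be a dict or the path of a two-column TSV (sample, pop).
    """
    from cyvcf2 import VCF

    if isinstance(popmap, str):
        pm = pd.read_csv(popmap, sep="\t", header=None, names=["sample", "pop"],
                         dtype=str)
        popmap = dict(zip(pm["sample"], pm["pop"]))
    vcf = VCF(path)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in popmap]
    if missing:
        raise ValueError(f"{path}: samples without population mapping: {missing}")
    loci, refs, alts = [], [], []
    for var in vcf:
        loci.append(var.ID or f"{var.CHROM}:{var.POS}")
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"{path}: record {loci[-1]} lacks the AD field")
        ad = np.maximum(ad, 0)
        refs.append(ad[:, 0])
        alts.append(ad[:, 1] if ad.shape[1] > 1 else np.zeros(len(samples), int))
    return ReadCountMatrix(
        loci=np.array(loci, dtype=object),
        individuals=np.array(samples, dtype=object),
        populations=np.array([popmap[s] for s in samples], dtype=object),
        ref=np.column_stack(refs) if refs else np.zeros((len(samples), 0), np.int32),
        alt=np.column_stack(alts) if alts else np.zeros((len(samples), 0), np.int32),
    )


def write_landmarks_csv(lms: LandmarkSet, path: str) -> None:
    cols = {"specimen": lms.specimens, "group": lms.groups}
    for j in range(morpho.N_LANDMARKS):
        cols[f"x{j + 1}"] = lms.coords[:, j, 0]
        cols[f"y{j + 1}"] = lms.coords[:, j, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_landmarks_csv(path: str) -> LandmarkSet:
    df = pd.read_csv(path, dtype={"specimen": str, "group": str})
    xcols = [f"x{j + 1}" for j in range(morpho.N_LANDMARKS)]
    ycols = [f"y{j + 1}" for j in range(morpho.N_LANDMARKS)]
    missing = [c for c in xcols + ycols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing landmark columns {missing}")
    bad = df[df[xcols + ycols].isna().any(axis=1)]
    if not bad.empty:
        raise ValueError(
            f"{path}: incomplete landmark rows for specimens "
            f"{bad['specimen'].tolist()}"
        )
    coords = np.stack(
        [df[xcols].to_numpy(float), df[ycols].to_numpy(float)], axis=2
    )
    return LandmarkSet(
        specimens=df["specimen"].to_numpy(dtype=object),
        groups=df["group"].to_numpy(dtype=object),
        coords=coords,
        side_flag=df["side"].to_numpy(dtype=object) if "side" in df.columns else None,
    )


def write_tps(lms: LandmarkSet, path: str) -> None:
    """TPS records (LM=12, ID=, SCALE=); image coordinates = coords / scale."""
    scale = lms.scale if lms.scale is not None else np.ones(lms.n_specimens)
    with open(path, "w") as fh:
        for i in range(lms.n_specimens):
            fh.write(f"LM={morpho.N_LANDMARKS}\n")
            for j in range(morpho.N_LANDMARKS):
                x, y = lms.coords[i, j] / scale[i]
                fh.write(f"{x:.6f} {y:.6f}\n")
            fh.write(f"ID={lms.specimens[i]}\n")
            fh.write(f"SCALE={scale[i]:.6f}\n")


def read_tps(path: str, group_map: Optional[dict] = None) -> LandmarkSet:
    """Read TPS records, honoring SCALE lines (coords × scale)."""
    if isinstance(group_map, str):
        gm = pd.read_csv(group_map, sep="\t", header=None,
                         names=["specimen", "group"], dtype=str)
        group_map = dict(zip(gm["specimen"], gm["group"]))
    specs, groups, configs = [], [], []
    cur: Optional[list] = None
    cur_id, cur_scale, n_expected = None, 1.0, 0
    line_no = 0

    def _flush():
        if cur is None:
            return
        if len(cur) != n_expected:
            raise ValueError(
                f"{path}: specimen {cur_id!r} has {len(cur)} landmarks, "
                f"expected {n_expected}"
            )
        sid = cur_id if cur_id is not None else f"spec_{len(specs):03d}"
        specs.append(sid)
        groups.append((group_map or {}).get(sid, "all"))
        configs.append(np.asarray(cur, dtype=float) * cur_scale)

    with open(path) as fh:
        for line in fh:
            line_no += 1
            line = line.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                _flush()
                n_expected = int(line.split("=", 1)[1])
                if n_expected != morpho.N_LANDMARKS:
                    raise ValueError(
                        f"{path}:{line_no}: LM={n_expected}, expected "
                        f"{morpho.N_LANDMARKS}"
                    )
                cur, cur_id, cur_scale = [], None, 1.0
            elif upper.startswith("ID="):
                cur_id = line.split("=", 1)[1]
            elif upper.startswith("SCALE="):
                cur_scale = float(line.split("=", 1)[1])
                # SCALE may appear after the coordinates; reapply on flush
            elif upper.startswith(("IMAGE=", "CURVES=", "POINTS=")):
                continue
            else:
                if cur is None:
                    raise ValueError(f"{path}:{line_no}: coordinates before LM=")
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{line_no}: malformed coordinate line")
                cur.append([float(parts[0]), float(parts[1])])
    _flush()
    if not specs:
        raise ValueError(f"{path}: no TPS records found")
    return LandmarkSet(
        specimens=np.array(specs, dtype=object),
        groups=np.array(groups, dtype=object),
        coords=np.stack(configs),
    )


def read_melanization_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"specimen": str, "group": str})
    return melan_stats.prepare_melanization_table(df)


def load_inputs(config) -> dict:
    """Load (or synthesize) the domain objects the configuration describes.

    Returns a dict with any of: rcm (+truth), landmarks (+truth),
    melanization (+truth).
    """
    cfg = load_config(config)
    out: dict = {}
    g = cfg.genetic
    if "synthetic" in g:
        syn = g["synthetic"]
        freqs = synthdata.sim_pop_frequencies(
            loci=int(syn.get("loci", 2000)),
            populations=syn.get("populations", ["early", "late"]),
            F=float(syn.get("F", 0.06)),
            p0_range=tuple(syn.get("p0_range", (0.05, 0.95))),
            seed=stage_seed(cfg.seed, "sim_frequencies"),
        )
        rcm, truth = synthdata.sim_read_counts(
            freqs,
            syn.get("n_per_pop", 25),
            coverage=float(syn.get("coverage", 8.0)),
            err=float(syn.get("err", 0.005)),
            missing_rate=float(syn.get("missing_rate", 0.1)),
            seed=stage_seed(cfg.seed, "sim_read_counts"),
        )
        out["rcm"], out["genetic_truth"] = rcm, truth
    elif "read_counts" in g:
        out["rcm"] = read_read_counts_tsv(g["read_counts"])
    elif "vcf" in g:
        if "popmap" not in g:
            raise ValueError("genetic.vcf requires genetic.popmap")
        out["rcm"] = read_vcf(g["vcf"], g["popmap"])

    m = cfg.morpho
    if "synthetic" in m:
        syn = m["synthetic"]
        groups = syn.get("groups", {"early": 20, "late": 20})
        rng = np.random.default_rng(stage_seed(cfg.seed, "sim_landmark_effects"))
        effects = syn.get("shape_effects")
        if effects is None and syn.get("effect_norm"):
            effects = {}
            for lab in groups:
                v = rng.normal(size=24)
                effects[lab] = v / np.linalg.norm(v) * float(syn["effect_norm"])
        allo = syn.get("allometric_vector")
        if allo is None and syn.get("allometry_norm"):
            v = rng.normal(size=24)
            allo = v / np.linalg.norm(v) * float(syn["allometry_norm"])
        lms, truth = synthdata.sim_landmarks(
            groups,
            shape_effects=effects,
            allometric_vector=allo,
            cs_range=tuple(syn.get("cs_range", (22.0, 28.0))),
            noise_sd=float(syn.get("noise_sd", 0.005)),
            seed=stage_seed(cfg.seed, "sim_landmarks"),
        )
        out["landmarks"], out["morpho_truth"] = lms, truth
    elif "landmarks_csv" in m:
        out["landmarks"] = read_landmarks_csv(m["landmarks_csv"])
    elif "tps" in m:
        out["landmarks"] = read_tps(m["tps"], m.get("group_map"))

    mel = cfg.melanization
    if "synthetic" in mel:
        syn = mel["synthetic"]
        df, truth = synthdata.sim_melanization(
            syn.get("groups", {"early": 25, "late": 25}),
            area_range=tuple(syn.get("area_range", (90.0, 150.0))),
            slope=float(syn.get("slope", 0.2)),
            group_offsets=syn.get("group_offsets"),
            noise_sd=float(syn.get("noise_sd", 1.0)),
            seed=stage_seed(cfg.seed, "sim_melanization"),
        )
        out["melanization"] = melan_stats.prepare_melanization_table(df)
        out["melanization_truth"] = truth
    elif "table" in mel:
        out["melanization"] = read_melanization_csv(mel["table"])
    return out


# ---------------------------------------------------------------------------
# orchestration

def _genetic_arm(cfg: PipelineConfig, inputs: dict, report: RunReport) -> None:
    rcm = inputs["rcm"]
    fspec = popstruct.FilterSpec(**cfg.genetic.get("filter", {}))
    filtered, removal_log = popstruct.filter_dataset(rcm, fspec)
    report.add("filter_removal_log", removal_log, "filter_dataset",
               **fspec.__dict__)
    if filtered.n_loci == 0:
        report.warnings.append("genetic arm: all sites removed by filtering")
        return
    mc = cfg.genetic["mcmc"]
    afp, gp = genomod.gibbs_allele_frequency(
        filtered,
        err=float(mc["err"]),
        steps=int(mc["steps"]),
        burnin=int(mc["burnin"]),
        thin=int(mc["thin"]),
        seed=stage_seed(cfg.seed, "gibbs_allele_frequency"),
    )
    inputs["afp"], inputs["gp"], inputs["filtered"] = afp, gp, filtered
    pm = pd.DataFrame(
        afp.posterior_mean.T, index=pd.Index(filtered.loci, name="locus"),
        columns=afp.populations,
    )
    report.add("allele_frequency_posterior_mean", pm.reset_index(),
               "gibbs_allele_frequency", **afp.mcmc_meta)

    pca = popstruct.genotype_pca(gp, n_axes=min(10, filtered.n_individuals - 1))
    scores = pd.DataFrame(
        pca.scores,
        columns=[f"PC{a + 1}" for a in range(pca.scores.shape[1])],
    )
    scores.insert(0, "individual", filtered.individuals)
    scores.insert(1, "population", filtered.populations)
    report.add("genotype_pca_scores", scores, "genotype_pca", **pca.meta)
    report.add(
        "genotype_pca_variance",
        pd.DataFrame(
            {
                "axis": [f"PC{a + 1}" for a in range(len(pca.variance_fraction))],
                "variance_fraction": pca.variance_fraction,
            }
        ),
        "genotype_pca",
    )

    gst = popstruct.pairwise_gst(afp)
    inputs["gst"] = gst
    report.add("gst_table2", gst.to_table2_frame().reset_index(names="population"),
               "pairwise_gst")
    report.add("gst_long", gst.to_long_frame(), "pairwise_gst")

    nm = cfg.genetic["nmds"]
    dims = min(int(nm["dims"]), len(gst.populations) - 1)
    if len(gst.populations) >= 3 and np.isfinite(gst.estimate).all():
        nmds = popstruct.nmds_embed(
            gst.estimate, dims=dims, restarts=int(nm["restarts"]),
            seed=stage_seed(cfg.seed, "nmds"),
        )
        nscores = pd.DataFrame(
            nmds.scores, columns=[f"NMDS{a + 1}" for a in range(dims)]
        )
        nscores.insert(0, "population", gst.populations)
        nscores["stress"] = nmds.stress
        report.add("gst_nmds", nscores, "nmds_embed", **nmds.meta)
    else:
        report.warnings.append("NMDS skipped: need >= 3 populations with defined G_ST")

    div = genomod.diversity_estimates(filtered, err=float(mc["err"]))
    report.add(
        "diversity",
        pd.DataFrame(
            {
                "population": div.populations,
                "n": div.n,
                "S": div.S,
                "pi": div.pi,
                "theta_w": div.theta_w,
                "theta_w_per_site": div.theta_w_per_site,
            }
        ),
        "diversity_estimates",
    )

    adm = cfg.genetic["admixture"]
    phm = popstruct.pseudo_haploid_sample(
        filtered, seed=stage_seed(cfg.seed, "pseudo_haploid")
    )
    k_values = list(range(int(adm["k_min"]), int(adm["k_max"]) + 1))
    if len(k_values) >= 3:
        sel, results = admix.run_admixture_scan(
            phm,
            k_values,
            replicates=int(adm["replicates"]),
            steps=int(adm["steps"]),
            burnin=int(adm["burnin"]),
            thin=int(adm["thin"]),
            alpha=float(adm["alpha"]),
            seed=stage_seed(cfg.seed, "admixture_scan"),
        )
        report.add("k_selection", sel.table, "evanno_delta_k", **{
            "replicates": adm["replicates"], "steps": adm["steps"],
            "burnin": adm["burnin"],
        })
        for k in k_values:
            aligned, _ = admix.align_replicates([r.Q for r in results[k]])
            qmean = np.mean(aligned, axis=0)
            qf = pd.DataFrame(
                qmean, columns=[f"cluster_{c + 1}" for c in range(k)]
            )
            qf.insert(0, "individual", filtered.individuals)
            qf.insert(1, "population", filtered.populations)
            report.add(f"admixture_q_K{k}", qf, "admixture_gibbs",
                       K=k, **{k2: adm[k2] for k2 in ("steps", "burnin", "alpha")})
    else:
        report.warnings.append("ΔK skipped: K range must span >= 3 values")


def _morpho_arm(cfg: PipelineConfig, inputs: dict, report: RunReport) -> None:
    lms = inputs["landmarks"]
    if cfg.morpho.get("reflect_side"):
        lms = morpho.reflect_sides(lms, cfg.morpho["reflect_side"])
    aligned = morpho.generalized_procrustes(
        lms, tangent_projection=bool(cfg.morpho.get("tangent_projection", False))
    )
    inputs["aligned"] = aligned
    if not aligned.converged:
        report.warnings.append("GPA did not converge")
    res = morpho.allometry_correction(aligned)
    inputs["shape_residuals"] = res
    report.add(
        "allometry",
        pd.DataFrame(
            {
                "coordinate": [f"{ax}{j + 1}" for ax in ("x", "y") for j in range(12)],
                "regression_vector": np.concatenate(
                    [res.regression_vector[0::2], res.regression_vector[1::2]]
                ),
            }
        ),
        "allometry_correction",
        percent_predicted=res.percent_predicted,
    )

    pca = morpho.shape_pca(res)
    nshow = min(5, pca.scores.shape[1])
    sc = pd.DataFrame(
        pca.scores[:, :nshow], columns=[f"PC{a + 1}" for a in range(nshow)]
    )
    sc.insert(0, "specimen", res.specimens)
    sc.insert(1, "group", res.groups)
    report.add("shape_pca_scores", sc, "shape_pca")
    report.add(
        "shape_pca_variance",
        pd.DataFrame(
            {
                "axis": [f"PC{a + 1}" for a in range(len(pca.variance_fraction))],
                "variance_fraction": pca.variance_fraction,
            }
        ),
        "shape_pca",
    )
    for axis in range(min(3, pca.scores.shape[1])):
        table = melan_stats.anova_with_tukey(pca.scores[:, axis], res.groups)
        report.add(
            f"shape_pc{axis + 1}_anova",
            pd.DataFrame(
                [{
                    "F": table.F, "df_between": table.df_between,
                    "df_within": table.df_within, "p": table.p,
                }]
            ),
            "one_way_anova",
            response=f"PC{axis + 1}",
        )
        report.add(f"shape_pc{axis + 1}_tukey", table.tukey, "tukey_hsd",
                   response=f"PC{axis + 1}")

    ellipses = morpho.group_mean_ellipses(pca.scores[:, :2], res.groups)
    report.add(
        "shape_pca_ellipses",
        pd.DataFrame(
            [
                {
                    "group": g,
                    "center_x": e.center[0], "center_y": e.center[1],
                    "semi_major": e.semi_axes[0], "semi_minor": e.semi_axes[1],
                    "angle_rad": e.angle_rad, "n": e.n,
                }
                for g, e in ellipses.items()
            ]
        ),
        "mean_confidence_ellipse",
    )

    if len(set(res.groups)) >= 2:
        cva = morpho.canonical_variates(res)
        ncv = cva.cv_scores.shape[1]
        cs = pd.DataFrame(
            cva.cv_scores, columns=[f"CV{a + 1}" for a in range(ncv)]
        )
        cs.insert(0, "specimen", res.specimens)
        cs.insert(1, "group", res.groups)
        report.add("cva_scores", cs, "canonical_variates")
        report.add(
            "cva_summary",
            pd.DataFrame(
                {
                    "axis": [f"CV{a + 1}" for a in range(ncv)],
                    "eigenvalue": cva.eigenvalues,
                    "percent_among_variance": cva.percent_among_variance,
                }
            ),
            "canonical_variates",
        )
        if ncv >= 2:
            cva_ell = morpho.group_mean_ellipses(cva.cv_scores[:, :2], res.groups)
            report.add(
                "cva_ellipses",
                pd.DataFrame(
                    [
                        {
                            "group": g,
                            "center_x": e.center[0], "center_y": e.center[1],
                            "semi_major": e.semi_axes[0],
                            "semi_minor": e.semi_axes[1],
                            "angle_rad": e.angle_rad, "n": e.n,
                        }
                        for g, e in cva_ell.items()
                    ]
                ),
                "mean_confidence_ellipse",
            )
        dist, pval = morpho.procrustes_distances(
            aligned,
            permutations=int(cfg.morpho["permutations"]),
            seed=stage_seed(cfg.seed, "procrustes_permutations"),
        )
        report.add("procrustes_distances", dist.reset_index(names="group"),
                   "procrustes_distances")
        report.add("procrustes_pvalues", pval.reset_index(names="group"),
                   "procrustes_distances",
                   permutations=cfg.morpho["permutations"])


def _melanization_arm(cfg: PipelineConfig, inputs: dict, report: RunReport) -> None:
    table = inputs["melanization"]
    fit = melan_stats.melanization_residuals(table)
    inputs["melanization_fit"] = fit
    report.add(
        "melanization_regression",
        pd.DataFrame(
            [{
                "R": fit.R, "p_value": fit.p_value, "slope": fit.slope,
                "intercept": fit.intercept, "status": fit.status,
            }]
        ),
        "melanization_residuals",
    )
    report.add("melanization_records", fit.records, "melanization_residuals")
    if fit.status == "ok":
        table_anova = melan_stats.anova_with_tukey(
            fit.records["residual_melanization"], fit.records["group"]
        )
        report.add(
            "melanization_anova",
            pd.DataFrame(
                [{
                    "F": table_anova.F, "df_between": table_anova.df_between,
                    "df_within": table_anova.df_within, "p": table_anova.p,
                }]
            ),
            "one_way_anova",
            response="residual_melanization",
        )
        report.add("melanization_tukey", table_anova.tukey, "tukey_hsd",
                   response="residual_melanization")


def run_full_pipeline(config, write: bool = True) -> RunReport:
    """Execute every arm the configuration has inputs for.

    Any stage failure raises with the stage name; tables produced before
    the failure are preserved on the exception's ``report`` attribute.
    """
    cfg = load_config(config)
    from . import __version__

    report = RunReport(
        provenance={
            "config": cfg.raw,
            "seed": cfg.seed,
            "version": __version__,
        }
    )
    inputs = load_inputs(cfg)
    stages = []
    if cfg.has_genetic_input():
        stages.append(("genetic", _genetic_arm))
    if cfg.has_morpho_input():
        stages.append(("morphometrics", _morpho_arm))
    if cfg.has_melanization_input():
        stages.append(("melanization", _melanization_arm))
    if not stages:
        raise ValueError("configuration provides no inputs for any arm")
    for name, fn in stages:
        try:
            fn(cfg, inputs, report)
        except Exception as exc:
            exc.report = report  # partial outputs preserved
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    report.provenance["inputs"] = sorted(inputs)
    if write:
        write_report(report, cfg.outdir)
    return report


def write_report(report: RunReport, outdir: str) -> list:
    """Write every table as TSV plus a human-readable summary (atomically)."""
    os.makedirs(outdir, exist_ok=True)
    if not os.access(outdir, os.W_OK):
        raise PermissionError(f"output directory {outdir} is not writable")
    written = []
    for name in sorted(report.tables):
        frame = report.tables[name]
        path = os.path.join(outdir, f"{name}.tsv")
        tmp = path + ".tmp"
        frame.to_csv(tmp, sep="\t", index=False, float_format="%.10g")
        os.replace(tmp, path)
        written.append(path)
    summary = os.path.join(outdir, "summary.txt")
    tmp = summary + ".tmp"
    with open(tmp, "w") as fh:
        fh.write("flightdiff run summary\n")
        fh.write(f"seed: {report.provenance.get('seed')}\n")
        fh.write(f"version: {report.provenance.get('version')}\n")
        fh.write("tables:\n")
        for name in sorted(report.tables):
            frame = report.tables[name]
            op = frame.attrs.get("operation", "?")
            params = frame.attrs.get("params", {})
            ptxt = ", ".join(f"{k}={v}" for k, v in sorted(params.items(), key=str))
            fh.write(f"  - {name}.tsv  [{op}]" + (f" ({ptxt})" if ptxt else "") + "\n")
        if report.warnings:
            fh.write("warnings:\n")
            for w in report.warnings:
                fh.write(f"  - {w}\n")
        else:
            fh.write("no warnings\n")
    os.replace(tmp, summary)
    written.append(summary)
    report.files = written
    manifest = os.path.join(outdir, "manifest.json")
    tmp = manifest + ".tmp"
    with open(tmp, "w") as fh:
        json.dump({"files": [os.path.basename(p) for p in written]}, fh, indent=1)
    os.replace(tmp, manifest)
    report.files.append(manifest)
    return report.files


def write_truth_json(truth, path: str) -> None:
    """Sidecar key-value file for synthetic ground truth (arrays as lists)."""
    def enc(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: enc(x) for k, x in v.items()}
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    payload = {}
    for key, val in truth.__dict__.items():
        if val is None:
            continue
        if key == "frequencies":
            payload[key] = {
                "loci": val.loci, "populations": val.populations,
                "F": val.F, "p0": enc(val.p0), "p": enc(val.p),
            }
        else:
            payload[key] = enc(val)
    with open(path, "w") as fh:
        json.dump(payload, fh)
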