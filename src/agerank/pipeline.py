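"""End-to-end orchestration: simulate -> root/delta-EP -> bin/rank -> tests.

A single INI config drives every stage.  One master seed deterministically
derives a per-stage seed (keyed by stage name), so any stage can be re-run
in isolation and a full re-run with the same config reproduces
byte-identical outputs; the manifest records a content hash per output
file to make that checkable.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import age_analysis, delta_ep, io_formats, matched_ranks, selection_tests
from . import synthetic_data as synth

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "deltaep", "rank", "age_tests", "het",
               "recomb", "dispersion", "fst", "beta")


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def _bool(v: str) -> bool:
    if v.lower() in ("1", "true", "yes", "on"):
        return True
    if v.lower() in ("0", "false", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def _positive_int(v: str) -> int:
    out = int(v)
    if out < 1:
        raise ValueError(f"must be >= 1, got {out}")
    return out


# section -> key -> (caster, default)
_SCHEMA: dict = {
    "pipeline": {
        "outdir": (str, "agerank_out"),
        "seed": (int, 1),
        "stages": (str, "simulate,deltaep,rank,age_tests,het,recomb,dispersion"),
    },
    "simulate": {
        "n": (_positive_int, 1000),
        "n2": (_positive_int, 1000),
        "sites_per_class": (_positive_int, 2000),
        "s_negative": (float, -0.01),
        "s_overdominant": (float, 0.05),
        "s_fixed_positive": (float, 0.02),
        "fixed_positive_count": (_positive_int, 200),
        "fixed_neutral_count": (_positive_int, 100),
        "n_genes": (_positive_int, 60),
        "max_gens": (int, 0),  # 0 -> default 20N
    },
    "deltaep": {
        "require_anc_ref": (_bool, True),
        "bootstrap_b": (_positive_int, 500),
    },
    "rank": {
        "target_bin_size": (_positive_int, 500),
        "singleton_k_max": (int, 8),
        "estimator": (str, "true"),
    },
    "age_tests": {
        "bootstrap_b": (_positive_int, 200),
        "old_age_threshold": (float, 200_000.0),
    },
    "het": {
        "min_k": (_positive_int, 100),
        "s_true": (float, 0.05),
        "target_bin_size": (_positive_int, 200),
    },
    "recomb": {
        "alternative": (str, "greater"),
        "map_segments": (_positive_int, 40),
    },
    "dispersion": {
        "replicates": (_positive_int, 200),
    },
    "fst": {
        "input": (str, ""),
        "min_pooled_k": (_positive_int, 10),
        "target_bin_size": (_positive_int, 200),
    },
    "beta": {
        "input_pos": (str, ""),
        "input_neg": (str, ""),
    },
}


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    values: dict = field(default_factory=dict)

    def get(self, section: str, key: str):
        return self.values[section][key]

    @property
    def outdir(self) -> Path:
        return Path(self.get("pipeline", "outdir"))

    @property
    def seed(self) -> int:
        return int(self.get("pipeline", "seed"))

    @property
    def stages(self) -> list[str]:
        raw = [s.strip() for s in self.get("pipeline", "stages").split(",") if s.strip()]
        return raw


def validate_config(path, overrides: dict | None = None) -> PipelineConfig:
    """Parse and validate an INI config; every error is reported at once.

    Unknown sections/keys, uncastable values and out-of-range values are
    all collected; defaults are applied for missing keys and echoed to the
    log.  ``overrides`` maps "section.key" -> raw string value.
    """
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise ConfigError([f"cannot read config file {path}"])
    errors: list[str] = []
    values: dict = {}
    raw: dict = {s: dict(parser.items(s)) for s in parser.sections()}
    for section in raw:
        if section not in _SCHEMA:
            errors.append(f"unknown section [{section}]")
    if overrides:
        for dotted, v in overrides.items():
            try:
                section, key = dotted.split(".", 1)
            except ValueError:
                errors.append(f"override {dotted!r} is not of the form section.key")
                continue
            raw.setdefault(section, {})[key] = str(v)
    for section, schema in _SCHEMA.items():
        values[section] = {}
        given = raw.get(section, {})
        for key in given:
            if key not in schema:
                errors.append(f"unknown key {key!r} in section [{section}]")
        for key, (cast, default) in schema.items():
            if key in given:
                try:
                    values[section][key] = cast(given[key])
                except ValueError as exc:
                    errors.append(f"[{section}] {key}: {exc}")
            else:
                values[section][key] = default
                logger.debug("config default applied: [%s] %s = %r", section, key, default)
    if not errors:
        cfg = PipelineConfig(values=values)
        unknown = [s for s in cfg.stages if s not in STAGE_ORDER]
        errors.extend(f"unknown stage {s!r}" for s in unknown)
    if errors:
        raise ConfigError(errors)
    return cfg


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Stage-name-keyed generator derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())]))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path, rng) -> list[Path]:
    sec = cfg.values["simulate"]
    config = synth.default_cohort_config(
        N=sec["n"], n2=sec["n2"], sites_per_class=sec["sites_per_class"],
        s_negative=sec["s_negative"], s_overdominant=sec["s_overdominant"])
    classes = dict(config.classes)
    classes["fixed_positive"] = synth.ClassSpec(
        model=synth.SelectionModel.additive(sec["s_fixed_positive"]),
        count=sec["fixed_positive_count"], ep_mean_ancestral=0.15,
        ep_mean_derived=0.65, fixed=True)
    classes["fixed_neutral"] = synth.ClassSpec(
        model=synth.SelectionModel.neutral(), count=sec["fixed_neutral_count"],
        ep_mean_ancestral=0.7, ep_mean_derived=0.25, fixed=True)
    config = synth.CohortConfig(
        N=config.N, n2=config.n2, classes=classes,
        max_gens=sec["max_gens"] or None, n_genes=sec["n_genes"])
    sites, ages = synth.simulate_cohort(config, rng)
    io_formats.write_site_table(sites, out / "sites.tsv")
    io_formats.write_age_table(ages, out / "ages.tsv")
    # synthetic genetic map over the simulated span (selection-independent)
    span = max(s.pos for s in sites) + 1000
    seg = cfg.get("recomb", "map_segments")
    pos = np.unique(np.linspace(1, span, seg, dtype=np.int64))
    rates = rng.lognormal(mean=0.0, sigma=0.7, size=pos.size)
    cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(pos) / 1e6)])
    map_df = pd.DataFrame({"position": pos, "rate_cM_Mb": rates, "map_cM": cum})
    _write_tsv(map_df, out / "map.tsv")
    # conditional heterozygote counts: het advantage s_true for the
    # overdominant class, s = 0 elsewhere
    s_true = cfg.get("het", "s_true")
    rows = []
    for s in sites:
        if s.k in (0, s.n2):
            # monomorphic in the sample: no heterozygotes possible
            rows.append((s.chrom, s.pos, s.k, s.n2, 0))
            continue
        s_site = s_true if (s.site_class == "nonsynonymous"
                            and (s.ep_alt or 0) > (s.ep_ref or 0)
                            and s.k < s.n2) else 0.0
        rows.append((s.chrom, s.pos, s.k, s.n2,
                     synth.sample_het_count_conditional(s.k, s.n2 // 2, s_site, rng)))
    het_df = pd.DataFrame(rows, columns=["chrom", "pos", "k", "n2", "het_count"])
    _write_tsv(het_df, out / "het_counts.tsv")
    positive = [s for s in sites if s.site_class == "nonsynonymous"
                and (s.ep_alt or 0) > (s.ep_ref or 0)]
    genes = synth.cohort_gene_table(positive)
    _write_tsv(genes, out / "genes.tsv")
    return [out / n for n in ("sites.tsv", "ages.tsv", "map.tsv",
                              "het_counts.tsv", "genes.tsv")]


def _read_rooted(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "rooted.tsv", sep="\t", na_values=["."],
                       keep_default_na=False, dtype={"chrom": str})


def _stage_deltaep(cfg: PipelineConfig, out: Path, rng) -> list[Path]:
    sites = io_formats.read_site_table(out / "sites.tsv")
    rooted, tally = delta_ep.root_sites(
        sites, require_anc_equals_ref=cfg.get("deltaep", "require_anc_ref"))
    logger.info("deltaep: rooting tally %s", dict(tally))
    rows = [{
        "chrom": r.chrom, "pos": r.pos, "ancestral": r.ancestral_allele,
        "derived": r.derived_allele, "derived_k": r.derived_k, "n2": r.site.n2,
        "delta_ep": r.delta_ep, "site_class": r.site.site_class,
        "is_cpg": int(bool(r.is_cpg)), "fixed": int(r.fixed_flag),
        "gene_id": r.site.gene_id,
    } for r in rooted]
    _write_tsv(pd.DataFrame(rows), out / "rooted.tsv")
    summary = delta_ep.summarize_classes(rooted, B=cfg.get("deltaep", "bootstrap_b"), rng=rng)
    _write_tsv(summary, out / "class_summary.tsv")
    return [out / "rooted.tsv", out / "class_summary.tsv"]


def _stage_rank(cfg: PipelineConfig, out: Path, rng) -> list[Path]:
    rooted = _read_rooted(out)
    ages = io_formats.read_age_table(out / "ages.tsv")
    est = cfg.get("rank", "estimator")
    ages = ages[ages["estimator"] == est]
    merged = rooted.merge(ages[["chrom", "pos", "age_gens"]], on=["chrom", "pos"])
    seg = merged[(merged["fixed"] == 0) & (merged["is_cpg"] == 0)]
    nulls = seg[seg["site_class"] == "noncoding_nonregulatory"]
    focal = seg[seg["site_class"] == "nonsynonymous"]
    if len(nulls) == 0 or len(focal) == 0:
        raise RuntimeError("rank stage needs non-empty focal and control sets")
    bins = matched_ranks.build_frequency_bins(
        nulls["derived_k"], nulls["age_gens"],
        target_bin_size=cfg.get("rank", "target_bin_size"),
        singleton_k_max=cfg.get("rank", "singleton_k_max"))
    keys = list(zip(focal["chrom"], focal["pos"]))
    df, n_unmatched = matched_ranks.rank_sites(
        focal["derived_k"], focal["age_gens"], bins, rng, keys=keys)
    logger.info("rank: %d focal sites unmatched", n_unmatched)
    df = df.assign(chrom=[k[0] for k in df["key"]], pos=[k[1] for k in df["key"]])
    df = df.drop(columns=["key"]).merge(
        focal[["chrom", "pos", "delta_ep"]], on=["chrom", "pos"])
    df = df[["chrom", "pos", "k", "value", "delta_ep", "bin_id", "null_size", "rank"]]
    df = df.rename(columns={"value": "age_gens"})
    _write_tsv(df, out / "ranks.tsv")
    bins_df = pd.DataFrame([{"bin_id": i, "k_lo": b.k_lo, "k_hi": b.k_hi, "size": b.size}
                            for i, b in enumerate(bins.bins)])
    _write_tsv(bins_df, out / "bins.tsv")
    return [out / "ranks.tsv", out / "bins.tsv"]


def _stage_age_tests(cfg: PipelineConfig, out: Path, rng) -> list[Path]:
    rooted = _read_rooted(out)
    ages = io_formats.read_age_table(out / "ages.tsv")
    ranks = pd.read_csv(out / "ranks.tsv", sep="\t", dtype={"chrom": str})
    bins_df = pd.read_csv(out / "bins.tsv", sep="\t")
    est = cfg.get("rank", "estimator")
    merged = rooted.merge(ages[ages["estimator"] == est][["chrom", "pos", "age_gens"]],
                          on=["chrom", "pos"])
    merged = merged[(merged["fixed"] == 0) & (merged["is_cpg"] == 0)]
    bin_set = matched_ranks.FrequencyBinSet(bins=tuple(
        matched_ranks.FrequencyBin(r.k_lo, r.k_hi, np.zeros(1))
        for r in bins_df.itertuples()))
    merged["freq_bin"] = bin_set.bin_index(merged["derived_k"].to_numpy())
    merged = merged[merged["freq_bin"] >= 0]
    control = merged["site_class"] == "noncoding_nonregulatory"
    anova_rows = []
    for sign, sel in (("negative", merged["delta_ep"] < 0),
                      ("positive", merged["delta_ep"] > 0)):
        sub = merged[control | (sel & (merged["site_class"] == "nonsynonymous"))]
        shared = sub.groupby("freq_bin")["site_class"].nunique()
        ok_bins = shared[shared == 2].index
        sub = sub[sub["freq_bin"].isin(ok_bins)]
        if sub.empty or sub["freq_bin"].nunique() < 2:
            logger.warning("age_tests: skipping ANOVA for %s (too few shared bins)", sign)
            continue
        res = age_analysis.anova_age_vs_control(
            sub["age_gens"].to_numpy(),
            (sub["site_class"] == "nonsynonymous").to_numpy(),
            sub["freq_bin"].to_numpy())
        for eff in ("class", "freq_bin"):
            anova_rows.append({
                "contrast": sign, "effect": eff,
                "ss": res.table.loc[eff, "ss"], "df": res.table.loc[eff, "df"],
                "F": res.table.loc[eff, "F"], "p": res.table.loc[eff, "p"],
                "boxcox_lambda": res.boxcox_lambda,
            })
    _write_tsv(pd.DataFrame(anova_rows), out / "anova.tsv")
    rooted_objs = _rooted_frame_to_objects(rooted)
    curve = age_analysis.age_rank_curve(rooted_objs, ranks,
                                        B=cfg.get("age_tests", "bootstrap_b"), rng=rng)
    _write_tsv(curve, out / "age_rank_curve.tsv")
    pos_ranks = ranks.loc[ranks["delta_ep"] > 0, "rank"]
    neg_ranks = ranks.loc[ranks["delta_ep"] < 0, "rank"]
    above, total, frac = age_analysis.fraction_above_half(pos_ranks)
    rows = [{"quantity": "positive_ranks_above_half", "count": above,
             "total": total, "value": frac}]
    m_neg, z_neg, p_neg = matched_ranks.mean_rank_ztest(neg_ranks, "less") \
        if len(neg_ranks) else (np.nan, np.nan, np.nan)
    m_pos, z_pos, p_pos = matched_ranks.mean_rank_ztest(pos_ranks, "greater") \
        if len(pos_ranks) else (np.nan, np.nan, np.nan)
    rows.append({"quantity": "negative_mean_rank", "count": len(neg_ranks),
                 "total": len(neg_ranks), "value": m_neg, "z": z_neg, "p": p_neg})
    rows.append({"quantity": "positive_mean_rank", "count": len(pos_ranks),
                 "total": len(pos_ranks), "value": m_pos, "z": z_pos, "p": p_pos})
    old_frac = age_analysis.old_age_fraction(
        ranks["age_gens"], cfg.get("age_tests", "old_age_threshold"))
    rows.append({"quantity": "old_age_fraction", "count": len(ranks),
                 "total": len(ranks), "value": old_frac})
    _write_tsv(pd.DataFrame(rows), out / "age_summary.tsv")
    return [out / n for n in ("anova.tsv", "age_rank_curve.tsv", "age_summary.tsv")]


def _rooted_frame_to_objects(rooted: pd.DataFrame) -> list[delta_ep.RootedSite]:
    out = []
    for r in rooted.itertuples(index=False):
        dep = None if pd.isna(r.delta_ep) else float(r.delta_ep)
        ep_anc, ep_der = (0.5, 0.5 + dep) if dep is not None else (None, None)
        if ep_der is not None:
            ep_anc -= max(0.0, ep_der - 1.0)
            ep_der = min(ep_der, 1.0)
            ep_anc, ep_der = np.clip([ep_anc, ep_der], 0.0, 1.0)
        site = io_formats.SiteRecord(
            chrom=str(r.chrom), pos=int(r.pos), ref_allele=str(r.ancestral),
            alt_allele=str(r.derived), anc_state=str(r.ancestral),
            k=int(r.derived_k), n2=int(r.n2),
            ep_ref=None if ep_anc is None else float(ep_anc),
            ep_alt=None if ep_der is None else float(ep_der),
            site_class=str(r.site_class), is_cpg=bool(r.is_cpg),
            gene_id=None if pd.isna(r.gene_id) else str(r.gene_id))
        out.append(delta_ep.RootedSite(
            site=site, ancestral_allele=site.ref_allele, derived_allele=site.alt_allele,
            derived_k=site.k, ep_ancestral=site.ep_ref, ep_derived=site.ep_alt))
    return out


def _stage_het(cfg: PipelineConfig, out: Path, rng) -> list[Path]:
    rooted = _read_rooted(out)
    het = pd.read_csv(out / "het_counts.tsv", sep="\t", dtype={"chrom": str})
    merged = rooted.merge(het[["chrom", "pos", "het_count"]], on=["chrom", "pos"])
    merged = merged[merged["fixed"] == 0]
    nulls = merged[merged["site_class"] == "noncoding_nonregulatory"]
    focal = merged[(merged["site_class"] == "nonsynonymous") & (merged["delta_ep"] > 0)]
    bins = matched_ranks.build_frequency_bins(
        nulls["derived_k"], nulls["het_count"].astype(float),
        target_bin_size=cfg.get("het", "target_bin_size"))
    res = selection_tests.het_excess_test(
        list(zip(focal["derived_k"], focal["het_count"])), bins, rng,
        min_k=cfg.get("het", "min_k"))
    df = pd.DataFrame([{"mean_rank": res.mean_rank, "z": res.z,
                        "p": res.p, "n_used": res.n_used}])
    _write_tsv(df, out / "het_test.tsv")
    return [out / "het_test.tsv"]


def _stage_recomb(cfg: PipelineConfig, out: Path, rng) -> list[Path]:
    rooted = _read_rooted(out)
    gmap = io_formats.read_genetic_map(out / "map.tsv")
    pos_class = rooted[(rooted["site_class"] == "nonsynonymous") & (rooted["delta_ep"] > 0)]
    fixed = pos_class.loc[pos_class["fixed"] == 1, "pos"]
    seg = pos_class.loc[pos_class["fixed"] == 0, "pos"]
    res = selection_tests.recomb_contrast(fixed.to_numpy(), seg.to_numpy(), gmap,
                                          alternative=cfg.get("recomb", "alternative"))
    df = pd.DataFrame([{"median_fixed": res.median_fixed,
                        "median_segregating": res.median_segregating,
                        "n_fixed": len(fixed), "n_segregating": len(seg),
                        "U": res.U, "p": res.p}])
    _write_tsv(df, out / "recomb_test.tsv")
    return [out / "recomb_test.tsv"]


def _stage_dispersion(cfg: PipelineConfig, out: Path, rng) -> list[Path]:
    genes = pd.read_csv(out / "genes.tsv", sep="\t", dtype={"chrom": str})
    results = selection_tests.dispersion_test(
        genes, rng, replicates=cfg.get("dispersion", "replicates"))
    df = pd.DataFrame([{"chrom": r.chrom, "observed_variance": r.observed_variance,
                        "mean_simulated_variance": float(r.simulated_variances.mean()),
                        "replicates": r.simulated_variances.size, "p": r.p}
                       for r in results])
    _write_tsv(df, out / "dispersion_test.tsv")
    return [out / "dispersion_test.tsv"]


def _stage_fst(cfg: PipelineConfig, out: Path, rng) -> list[Path]:
    path = cfg.get("fst", "input")
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    # expected columns: chrom pos role k1 n1 k2 n2 (role: focal|control)
    recs = [(r.role, selection_tests.FstRecord((r.chrom, r.pos), int(r.k1), int(r.n1),
                                               int(r.k2), int(r.n2)))
            for r in table.itertuples(index=False)]
    nulls = [(rec.pooled_k, rec.fst) for role, rec in recs if role == "control"
             and np.isfinite(rec.fst)]
    focals = [(rec.pooled_k, rec.fst) for role, rec in recs if role == "focal"]
    bins = matched_ranks.build_frequency_bins(
        [k for k, _ in nulls], [f for _, f in nulls],
        target_bin_size=cfg.get("fst", "target_bin_size"))
    mean_rank, W, p, n_used = selection_tests.fst_rank_test(
        focals, bins, rng, min_pooled_k=cfg.get("fst", "min_pooled_k"))
    df = pd.DataFrame([{"mean_rank": mean_rank, "W": W, "p": p, "n_used": n_used}])
    _write_tsv(df, out / "fst_test.tsv")
    return [out / "fst_test.tsv"]


def _stage_beta(cfg: PipelineConfig, out: Path, rng) -> list[Path]:
    pos = pd.read_csv(cfg.get("beta", "input_pos"), sep="\t")["score"]
    neg = pd.read_csv(cfg.get("beta", "input_neg"), sep="\t")["score"]
    mean_pos, mean_neg, U, p = selection_tests.beta_compare(pos, neg)
    df = pd.DataFrame([{"mean_pos": mean_pos, "mean_neg": mean_neg, "U": U, "p": p}])
    _write_tsv(df, out / "beta_test.tsv")
    return [out / "beta_test.tsv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "deltaep": _stage_deltaep,
    "rank": _stage_rank,
    "age_tests": _stage_age_tests,
    "het": _stage_het,
    "recomb": _stage_recomb,
    "dispersion": _stage_dispersion,
    "fst": _stage_fst,
    "beta": _stage_beta,
}

# inputs each stage needs on disk before it can run (within outdir unless external)
_STAGE_INPUTS = {
    "simulate": (),
    "deltaep": ("sites.tsv",),
    "rank": ("rooted.tsv", "ages.tsv"),
    "age_tests": ("rooted.tsv", "ages.tsv", "ranks.tsv", "bins.tsv"),
    "het": ("rooted.tsv", "het_counts.tsv"),
    "recomb": ("rooted.tsv", "map.tsv"),
    "dispersion": ("genes.tsv",),
    "fst": ("rooted.tsv",),
    "beta": (),
}


def run_pipeline(config: PipelineConfig) -> tuple[int, dict]:
    """Run the configured stages in dependency order.

    Returns (exit status, manifest).  The manifest lists every output file
    with a sha256 content hash; on stage failure the status is nonzero,
    partial outputs are retained and the manifest marks the failure point.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in config.stages]
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    # up-front input validation: external inputs must exist before anything runs
    errors = []
    for stage in stages:
        if stage == "fst" and not config.get("fst", "input"):
            errors.append("fst stage enabled but [fst] input not set")
        if stage == "beta" and not (config.get("beta", "input_pos")
                                    and config.get("beta", "input_neg")):
            errors.append("beta stage enabled but [beta] inputs not set")
    for stage in stages:
        if stage == "fst" and config.get("fst", "input") \
                and not Path(config.get("fst", "input")).exists():
            errors.append(f"fst input {config.get('fst', 'input')} does not exist")
    if "simulate" not in stages:
        for stage in stages:
            for name in _STAGE_INPUTS[stage]:
                if not (out / name).exists():
                    errors.append(f"stage {stage!r} needs missing input {name}")
    if errors:
        manifest["stages"] = {s: "not-run" for s in stages}
        manifest["errors"] = errors
        _write_manifest(manifest, out)
        return 1, manifest
    status = 0
    for stage in stages:
        rng = stage_rng(config.seed, stage)
        try:
            outputs = _STAGE_FUNCS[stage](config, out, rng)
        except Exception as exc:  # noqa: BLE001 - manifest must record the failure
            logger.exception("stage %s failed", stage)
            manifest["stages"][stage] = f"failed: {exc}"
            status = 1
            break
        manifest["stages"][stage] = "ok"
        for p in outputs:
            manifest["outputs"][p.name] = _sha256(p)
    _write_manifest(manifest, out)
    return status, manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
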