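"""End-to-end pipeline: genotyping -> diversity statistics -> migrant
detection -> genetic distances -> spatial dispersal.

A single master seed derives every stage seed, so a fixed configuration
yields byte-identical output bundles.  All outputs are plain text (TSV /
JSON) for diffability; stage timings are logged to standard error and a
MANIFEST.json records which stages completed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assignment as asg
from . import dispersal as disp
from . import distance as dist
from . import genotyping as gt
from . import popgen as pg
from . import synthetic as syn

log = logging.getLogger("tigerpop")

STAGES = ("genotype", "stats", "assign", "distance", "dispersal", "report")


@dataclass
class PipelineConfig:
    """All stage parameters with full-scale defaults.

    The admixture chain defaults (burn-in 100,000 / 1,000,000 recorded
    sweeps / 10 runs per K over K = 1..10) are the full analysis
    settings; the packaged fixture configuration scales them down so the
    end-to-end run finishes in seconds.
    """

    input_dir: str = "."
    output_dir: str = "out"
    seed: int = 0
    # genotyping
    min_hom: int = 3
    min_het: int = 2
    min_alleles: int = 14
    max_mismatch: int = 1
    # popgen tests
    hwe_n_mc: int = 10000
    ld_n_perm: int = 10000
    null_n_mc: int = 1000
    alpha: float = 0.05
    # assignment
    zero_freq: float = 0.01
    n_sim_exclusion: int = 10000
    n_sim_f0: int = 10000
    f0_threshold: float = 0.95
    tie_window: float = 0.1
    q_admix_window: tuple[float, float] = (0.4, 0.6)
    structure_burn_in: int = 100_000
    structure_reps: int = 1_000_000
    structure_runs_per_k: int = 10
    structure_k_range: tuple[int, int] = (1, 10)
    migprior: float = 0.05
    gensback: int = 2
    popinfo_burn_in: int = 200
    popinfo_reps: int = 800
    # distance
    mantel_n_perm: int = 9999
    use_boundary: bool = True
    # dispersal
    cell_km: float = 14.0
    period_mode: str = disp.CUMULATIVE

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update(overrides)
        for key in ("q_admix_window", "structure_k_range"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["q_admix_window"] = list(self.q_admix_window)
        doc["structure_k_range"] = list(self.structure_k_range)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_json(doc, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1, default=float)
        fh.write("\n")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on the fixture in ``config.input_dir``.

    Returns a result dictionary; writes the TSV/JSON bundle plus a
    human-readable report and MANIFEST.json into ``config.output_dir``.
    On stage failure, partial outputs are retained and the MANIFEST
    records the completion state before the error is re-raised.
    """
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {"seed": config.seed, "stage_seeds": seeds, "completed": []}
    results: dict = {}

    def finish_stage(name: str, t0: float) -> None:
        manifest["completed"].append(name)
        log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)

    try:
        for stage in STAGES[:-1]:
            t0 = time.perf_counter()
            globals()[f"_stage_{stage}"](config, indir, outdir, seeds[stage], results)
            finish_stage(stage, t0)
        t0 = time.perf_counter()
        _write_report(config, outdir, results)
        finish_stage("report", t0)
    except Exception as exc:
        manifest["error"] = str(exc)
        _write_json(manifest, outdir / "MANIFEST.json")
        if isinstance(exc, StageError):
            raise
        stage = STAGES[len(manifest["completed"])]
        raise StageError(stage, exc) from exc
    _write_json(manifest, outdir / "MANIFEST.json")
    return results


# ---------------------------------------------------------------------------
# stages


def _stage_genotype(config, indir, outdir, seed, results) -> None:
    rep_df = pd.read_csv(indir / "replicates.csv")
    samples = pd.read_csv(indir / "samples.csv").set_index("sample_id")
    replicates = syn.frame_to_replicates(rep_df)
    by_sample: dict[str, list] = {}
    for rep in replicates:
        by_sample.setdefault(rep.sample_id, []).append(rep)
    loci = list(dict.fromkeys(rep_df["locus"]))

    sex_calls: dict[str, str] = {}
    sex_path = indir / "sex_markers.csv"
    if sex_path.exists():
        sex_df = pd.read_csv(sex_path)
        for sid, grp in sex_df.groupby("sample_id"):
            sex_calls[str(sid)] = gt.assign_sex(
                list(zip(grp["zfx"], grp["dby7"])),
                positive_control_ok=bool(grp["positive_control_ok"].all()),
                negative_control_clean=bool(grp["negative_control_clean"].all()),
            )

    consensus = [
        gt.call_consensus(reps, config.min_hom, config.min_het, loci=loci)
        for _, reps in sorted(by_sample.items())
    ]
    usable = [c for c in consensus if gt.filter_usable(c, config.min_alleles)]
    metadata = {
        sid: {
            "population": samples.loc[sid, "population"],
            "lon": samples.loc[sid, "lon"],
            "lat": samples.loc[sid, "lat"],
        }
        for sid in samples.index
    }
    individuals = gt.match_individuals(usable, config.max_mismatch, metadata)
    for ind in individuals:
        calls = {s: sex_calls.get(s, "unknown") for s in ind.member_sample_ids}
        votes = [v for v in calls.values() if v != "unknown"]
        ind.sex = votes[0] if votes else "unknown"

    rows = []
    for ind in individuals:
        lon = np.mean([c[0] for c in ind.coordinates]) if ind.coordinates else np.nan
        lat = np.mean([c[1] for c in ind.coordinates]) if ind.coordinates else np.nan
        rows.append(
            {
                "individual_id": ind.individual_id,
                "population": ind.population_label,
                "sex": ind.sex,
                "n_samples": ind.n_samples,
                "typed_loci": len(ind.typed_loci()),
                "lon": lon,
                "lat": lat,
            }
        )
    _write_tsv(pd.DataFrame(rows), outdir / "individuals.tsv")
    results["loci"] = loci
    results["n_samples"] = len(consensus)
    results["n_usable"] = len(usable)
    results["individuals"] = individuals


def _stage_stats(config, indir, outdir, seed, results) -> None:
    individuals = results["individuals"]
    freqs = pg.allele_frequencies(individuals)
    results["freqs"] = freqs

    tables = []
    for pop in sorted(freqs.populations):
        t = pg.locus_stats(freqs, pop)
        t.insert(0, "population", pop)
        tables.append(t)
    _write_tsv(pd.concat(tables, ignore_index=True), outdir / "locus_stats.tsv")

    curves = []
    for pop in sorted(freqs.populations):
        c = pg.cumulative_pid(freqs, pop)
        c.insert(0, "population", pop)
        curves.append(c)
    _write_tsv(pd.concat(curves, ignore_index=True), outdir / "pid_curve.tsv")

    # pooled-sample HWE / LD / null-allele screen
    rng = np.random.SeedSequence(seed)
    sub = rng.generate_state(4) % (2**31)
    pooled_calls: dict[str, list] = {}
    for ind in individuals:
        for loc, call in ind.genotype.items():
            if call is not None:
                pooled_calls.setdefault(loc, []).append(call)
    loci = results["loci"]
    qc_rows = []
    hwe_ps = []
    for i, loc in enumerate(loci):
        calls = pooled_calls.get(loc, [])
        p_hwe = pg.hwe_exact_test(calls, n_mc=config.hwe_n_mc, seed=int(sub[0]) + i)
        r, p_hom, flagged = pg.null_allele_check(
            calls, n_mc=config.null_n_mc, seed=int(sub[1]) + i, alpha=config.alpha
        )
        hwe_ps.append(p_hwe)
        qc_rows.append(
            {
                "locus": loc,
                "n": len(calls),
                "hwe_p": p_hwe,
                "brookfield_r": r,
                "excess_hom_p": p_hom,
                "null_allele_flag": flagged,
            }
        )
    qc = pd.DataFrame(qc_rows)
    qc["hwe_reject_holm"] = pg.sequential_bonferroni(qc["hwe_p"], config.alpha)

    ld_rows = []
    ld_ps = []
    for i, (la, lb) in enumerate(combinations(loci, 2)):
        a = []
        b = []
        for ind in individuals:
            ca, cb = ind.genotype.get(la), ind.genotype.get(lb)
            a.append(ca)
            b.append(cb)
        try:
            p = pg.ld_permutation_test(
                a, b, n_perm=config.ld_n_perm, seed=int(sub[2]) + i
            )
        except ValueError:
            p = np.nan
        ld_rows.append({"locus_a": la, "locus_b": lb, "ld_p": p})
        ld_ps.append(p)
    ld = pd.DataFrame(ld_rows)
    ok = ld["ld_p"].notna()
    reject = np.zeros(len(ld), dtype=bool)
    if ok.any():
        reject[ok.to_numpy()] = pg.sequential_bonferroni(
            ld.loc[ok, "ld_p"], config.alpha
        )
    ld["ld_reject_holm"] = reject
    _write_tsv(qc, outdir / "locus_quality.tsv")
    _write_tsv(ld, outdir / "ld_tests.tsv")
    results["locus_quality"] = qc
    results["ld_tests"] = ld


def _stage_assign(config, indir, outdir, seed, results) -> None:
    individuals = results["individuals"]
    freqs = results["freqs"]
    pops = sorted(freqs.populations)
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(4) % (2**31)

    # admixture clustering + Evanno
    loci = results["loci"]
    geno, _ = asg.encode_genotypes([ind.genotype for ind in individuals], loci)
    cfg = asg.AdmixtureConfig(
        burn_in=config.structure_burn_in,
        reps=config.structure_reps,
        n_runs_per_k=config.structure_runs_per_k,
        k_range=config.structure_k_range,
        migprior=config.migprior,
        gensback=config.gensback,
        seed=int(sub[0]),
    )
    runs, per_k = asg.run_k_scan(geno, cfg)
    evanno = asg.evanno_delta_k(runs)
    _write_tsv(evanno.table.assign(selected_K=evanno.selected_k), outdir / "evanno.tsv")
    k_use = 2 if 2 in per_k else evanno.selected_k
    q_runs = per_k[k_use]
    q_mean = np.mean([r.q for r in q_runs], axis=0)
    q_df = pd.DataFrame(
        q_mean, columns=[f"cluster{j + 1}" for j in range(q_mean.shape[1])]
    )
    q_df.insert(0, "individual_id", [ind.individual_id for ind in individuals])
    _write_tsv(q_df, outdir / "q_matrix.tsv")

    # ancestry model with declared origins
    declared = [pops.index(ind.population_label) for ind in individuals]
    popinfo = asg.popinfo_migrant_model(
        geno,
        declared,
        cfg,
        burn_in=config.popinfo_burn_in,
        reps=config.popinfo_reps,
        seed=int(sub[1]),
    )

    # per-individual exclusion + F0 tests and classification
    rows = []
    records = []
    for i, ind in enumerate(individuals):
        calls = ind.genotype
        home = ind.population_label
        excl = {
            pop: asg.exclusion_test(
                calls,
                pop,
                freqs,
                n_sim=config.n_sim_exclusion,
                seed=int(sub[2]) + 97 * i + pops.index(pop),
                zero_freq=config.zero_freq,
                leave_one_out=(pop == home),
            )
            for pop in pops
        }
        lam, f0 = asg.f0_migrant_test(
            calls,
            home,
            freqs,
            n_sim=config.n_sim_f0,
            seed=int(sub[3]) + 131 * i,
            zero_freq=config.zero_freq,
        )
        excluded = {pop for pop, p in excl.items() if p < config.alpha}
        cands, cand_probs = asg.top_localities(
            excl, excluded=excluded, tie_window=config.tie_window
        )
        rec = asg.AssignmentRecord(
            individual_id=ind.individual_id,
            sampling_locality=home,
            exclusion_p=excl,
            lambda_ratio=lam,
            f0_migrant_probability=f0,
            q=q_mean[i],
            q_home=float(q_mean[i][0]),
            popinfo_migrant_posterior=float(popinfo.loc[i, "p_migrant"]),
            candidate_localities=cands,
            candidate_probs=cand_probs,
        )
        rec.classification = asg.classify_migrants(
            rec, config.q_admix_window, config.f0_threshold
        )
        records.append(rec)
        rows.append(
            {
                "individual_id": ind.individual_id,
                "GO": home,
                "Q": round(rec.q_home, 3),
                "GLOP": "/".join(cands) if cands else "-",
                "GHAP": "/".join(f"{p:.3f}" for p in cand_probs) if cands else "-",
                "F0": round(f0, 3),
                "SMP": round(rec.popinfo_migrant_posterior, 3),
                "FC": rec.classification,
            }
        )
    table = pd.DataFrame(rows)
    _write_tsv(table, outdir / "assignment.tsv")
    results["assignment"] = table
    results["assignment_records"] = records
    results["evanno"] = evanno
    results["q_mean"] = q_mean


def _stage_distance(config, indir, outdir, seed, results) -> None:
    individuals = results["individuals"]
    boundary = None
    bpath = indir / "boundary.geojson"
    if bpath.exists():
        with open(bpath) as fh:
            doc = json.load(fh)
        geom = doc.get("geometry", doc)
        boundary = [tuple(p) for p in geom["coordinates"]]
    elif config.use_boundary:
        raise FileNotFoundError(
            f"boundary analyses requested but {bpath} does not exist "
            "(set use_boundary: false to skip them)"
        )

    ids = [ind.individual_id for ind in individuals]
    calls_list = [ind.genotype for ind in individuals]
    da = dist.da_matrix(calls_list, ids)

    pooled = pg.allele_frequencies(individuals, by_population=False)
    ref = {
        loc: pooled.frequencies("pooled", loc) for loc in pooled.loci("pooled")
    }
    het_rows = []
    for ind in individuals:
        het_rows.append(
            {
                "individual_id": ind.individual_id,
                "HL": dist.hl_index(ind.genotype, ref),
                "IR": dist.ir_index(ind.genotype, ref),
            }
        )
    _write_tsv(pd.DataFrame(het_rows), outdir / "heterozygosity.tsv")

    lons = [np.mean([c[0] for c in ind.coordinates]) for ind in individuals]
    lats = [np.mean([c[1] for c in ind.coordinates]) for ind in individuals]
    euclid = dist.euclid_matrix(lons, lats)
    pair_rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pair_rows.append(
                {
                    "ind_a": ids[i],
                    "ind_b": ids[j],
                    "DA": da.iloc[i, j],
                    "euclid_km": euclid[i, j],
                }
            )
    pairs = pd.DataFrame(pair_rows)

    report = {}
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(2) % (2**31)
    report["euclid_km"] = dist.fit_distance_models(
        da.to_numpy(), euclid, "euclid_km",
        n_perm=config.mantel_n_perm, seed=int(sub[0]),
    ).to_dict()
    if boundary is not None:
        bkm = [
            dist.distance_to_polyline_km((lon, lat), boundary)
            for lon, lat in zip(lons, lats)
        ]
        bdiff = dist.boundary_diff_matrix(bkm)
        pairs["boundary_diff_km"] = bdiff[np.triu_indices(len(ids), k=1)]
        report["boundary_diff_km"] = dist.fit_distance_models(
            da.to_numpy(), bdiff, "boundary_diff_km",
            n_perm=config.mantel_n_perm, seed=int(sub[1]),
        ).to_dict()
    _write_tsv(pairs, outdir / "distances.tsv")
    _write_json(report, outdir / "model_report.json")
    results["distance_report"] = report
    results["da"] = da


def _stage_dispersal(config, indir, outdir, seed, results) -> None:
    occ = pd.read_csv(indir / "occurrences.csv")
    track, speed, trend = disp.analyze_occurrences(
        occ, cell_km=config.cell_km, mode=config.period_mode
    )
    centers = pd.DataFrame(
        {
            "period": track.labels,
            "end_year": track.end_years,
            "lon": track.lons,
            "lat": track.lats,
        }
    )
    steps = [np.nan] + [
        dist.haversine_km(track.lons[i], track.lats[i], track.lons[i + 1], track.lats[i + 1])
        for i in range(len(track) - 1)
    ]
    centers["step_km"] = steps
    _write_tsv(centers, outdir / "centers.tsv")
    _write_json({**speed, **trend, "mode": config.period_mode}, outdir / "trend.json")
    results["track"] = track
    results["speed"] = speed
    results["trend"] = trend


def _write_report(config, outdir, results) -> None:
    lines = []
    lines.append("tigerpop pipeline report")
    lines.append("=" * 40)
    lines.append("")
    lines.append("Samples and individuals")
    lines.append("-" * 40)
    lines.append(f"genotyped samples: {results['n_samples']}")
    lines.append(f"usable genotypes (>= {config.min_alleles} alleles): {results['n_usable']}")
    inds = results["individuals"]
    pops = sorted({i.population_label for i in inds})
    for pop in pops:
        sub = [i for i in inds if i.population_label == pop]
        sexes = pd.Series([i.sex for i in sub]).value_counts().to_dict()
        lines.append(f"{pop}: {len(sub)} individuals {sexes}")
    lines.append("")
    lines.append("Migrant detection")
    lines.append("-" * 40)
    table = results["assignment"]
    lines.append(table.to_string(index=False))
    migrants = table[table["FC"] != "-"]
    rate = 100.0 * len(migrants) / len(table) if len(table) else 0.0
    lines.append(f"flagged migrants: {len(migrants)}/{len(table)} ({rate:.2f}%)")
    lines.append(f"Evanno selected K: {results['evanno'].selected_k}")
    lines.append("")
    lines.append("Dispersal")
    lines.append("-" * 40)
    speed, trend = results["speed"], results["trend"]
    lines.append(
        f"speed: {speed['mean_step_km']:.2f} +/- {speed['sd_step_km']:.2f} km per interval"
    )
    lines.append(f"net displacement: {speed['net_displacement_km']:.2f} km")
    lines.append(
        f"longitude trend: slope={trend['slope_deg_per_year']:.4f} deg/yr, "
        f"R^2={trend['r_squared']:.3f}, p={trend['p_value']:.3g}"
    )
    with open(outdir / "report.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")
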