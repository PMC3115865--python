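"""End-to-end orchestration: diversity -> selfing -> bottleneck (gated on
s_hat = 0) -> differentiation -> predictors (with the ref+hol merge rule) ->
all-subsets model selection -> category contrasts.

The single run seed fans out to independent per-stage substreams
(`numpy.random.SeedSequence.spawn`), so any stage can be rerun in isolation
and the whole bundle is deterministic for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import differentiation as df
from . import mating, modelsel, predictors
from .bottleneck import TPMParams, bottleneck_table
from .popdata import GenotypeTable, HaplotypeTable, SiteTable, validate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    seed: int = 0
    rarefaction_copies: int = dv.DEFAULT_RAREFACTION_COPIES
    mantel_permutations: int = 10_000
    contrast_permutations: int = 1000
    selfing_permutations: int = 1000
    merge_permutations: int = 10_000
    bottleneck_reps: int = 1000
    tpm: TPMParams = field(default_factory=TPMParams)
    aic_convention: str = "aicc"
    alpha: float = 0.05
    quantile: float = 0.85
    display_threshold: float = 0.05
    run_bottleneck: bool = True

    def __post_init__(self) -> None:
        for nm in (
            "mantel_permutations",
            "contrast_permutations",
            "selfing_permutations",
            "merge_permutations",
        ):
            if getattr(self, nm) < 99:
                raise ValueError(f"{nm} must be >= 99")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _stage_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def run_pipeline(
    geno: GenotypeTable,
    sites: SiteTable,
    haps: HaplotypeTable | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full analysis and return the result bundle (a dict of tables).

    Keys: validation, diversity, selfing, bottleneck, fst, fst_linearized,
    geo, mantel, mst, predictors, models, contrasts, log.
    """
    cfg = config or PipelineConfig()
    rngs = _stage_rngs(
        cfg.seed, ["selfing", "bottleneck", "mantel", "merge", "contrast"]
    )
    log: list[str] = [f"seed={cfg.seed}", f"config={asdict(cfg)}"]
    bundle: dict = {"config": cfg, "sites": sites}

    issues = validate_dataset(geno, sites, haps)
    fatal = [i for i in issues if i.level == "fatal"]
    if fatal:
        raise ValueError(
            "validation failed: " + "; ".join(i.message for i in fatal)
        )
    bundle["validation"] = issues

    # diversity + selfing ---------------------------------------------------
    div = dv.diversity_table(geno, haps, g_nuc=cfg.rarefaction_copies)
    selfing = mating.selfing_table(
        geno, n_perm=cfg.selfing_permutations, rng=rngs["selfing"]
    )
    div["s"] = selfing["s_hat"]
    bundle["diversity"] = div
    bundle["selfing"] = selfing
    log.append(f"diversity: {len(div)} sites")

    # bottleneck, only for populations with an estimated selfing rate of zero
    if cfg.run_bottleneck:
        eligible = selfing.index[selfing["s_hat"] == 0].tolist()
        log.append(f"bottleneck-eligible (s_hat=0): {len(eligible)} sites")
        bundle["bottleneck"] = bottleneck_table(
            geno,
            eligible,
            tpm=cfg.tpm,
            n_reps=cfg.bottleneck_reps,
            alpha=cfg.alpha,
            rng=rngs["bottleneck"],
        )

    # differentiation -------------------------------------------------------
    fst = df.pairwise_fst(geno)
    lin = df.linearize_fst(fst)
    common = [c for c in fst.codes if c in sites.codes]
    geo = df.geo_distance_matrix(
        SiteTable(sites.frame.loc[common])
    )
    order = [geo.codes.index(c) for c in common]
    sub = [fst.codes.index(c) for c in common]
    lin_c = df.DistanceMatrix(
        codes=common, values=lin.values[np.ix_(sub, sub)], kind="linearized_fst"
    )
    geo_c = df.DistanceMatrix(
        codes=common, values=geo.values[np.ix_(order, order)], kind="geographic_km"
    )
    r, p = df.mantel_test(
        geo_c, lin_c, n_perm=cfg.mantel_permutations, rng=rngs["mantel"]
    )
    bundle["fst"] = fst
    bundle["fst_linearized"] = lin
    bundle["geo"] = geo_c
    bundle["mantel"] = {"r": r, "p": p, "n_perm": cfg.mantel_permutations}
    bundle["mst"] = df.minimum_spanning_tree(lin)
    bundle["overall_fst"] = df.wc_fst(geno)
    if haps is not None:
        bundle["overall_fst_mt"], bundle["fst_mt"] = df.haplotype_fst(haps)
    log.append(f"mantel r={r:.4f} p={p:.4g}")

    # predictors ------------------------------------------------------------
    pred = predictors.predictor_table(
        sites,
        div=div,
        q=cfg.quantile,
        n_perm=cfg.merge_permutations,
        rng=rngs["merge"],
    )
    bundle["predictors"] = pred
    merged = set(pred["expansion"].dropna()) == {"exp", "ref+hol"}
    log.append(f"expansion levels merged: {merged}")

    # model selection -------------------------------------------------------
    data = pred.join(div, how="inner")
    data["asin_H_E"] = np.arcsin(np.sqrt(data["H_E"].clip(0, 1)))
    responses = [
        ("asin_H_E", "H_E (arcsin-transformed)"),
        ("A", "rarefied allelic richness"),
        ("s", "selfing estimate"),
        ("H_mt", "rarefied haplotype number"),
    ]
    cand = [
        c for c in ("lim_km", "marg", "bar", "bio", "size", "expansion")
        if c in data.columns
    ]
    models = {}
    for col, label in responses:
        if col not in data.columns or data[col].notna().sum() < 10:
            log.append(f"model selection skipped for {label}: too few cases")
            continue
        models[col] = modelsel.all_subsets_selection(
            data[col],
            data,
            predictors=cand,
            convention=cfg.aic_convention,
            display_threshold=cfg.display_threshold,
        )
    bundle["models"] = models

    # category contrasts ----------------------------------------------------
    contrasts = []
    groupings: dict[str, dict[str, bool]] = {}
    for f in ("bar", "bio", "size", "lim_group", "marg_group"):
        if f in pred.columns:
            groupings[f] = {
                c: bool(pred.loc[c, f]) for c in fst.codes if c in pred.index
            }
    exp_cls = pred["expansion"].astype(str)
    levels = sorted(set(exp_cls.dropna()))
    for i, la in enumerate(levels):
        for lb in levels[i + 1 :]:
            pair = [c for c in fst.codes if exp_cls.get(c) in (la, lb)]
            sel = [fst.codes.index(c) for c in pair]
            m2 = df.DistanceMatrix(
                codes=pair, values=fst.values[np.ix_(sel, sel)], kind="fst"
            )
            try:
                contrasts.append(
                    df.category_fst_contrast(
                        m2,
                        [c for c in pair if exp_cls[c] == la],
                        n_perm=cfg.contrast_permutations,
                        rng=rngs["contrast"],
                        label=f"{la} vs {lb}",
                    )
                )
            except ValueError as e:
                log.append(f"contrast {la} vs {lb} skipped: {e}")
    for f, member in groupings.items():
        try:
            contrasts.append(
                df.category_fst_contrast(
                    bundle["fst"],
                    member,
                    n_perm=cfg.contrast_permutations,
                    rng=rngs["contrast"],
                    label=f,
                )
            )
        except ValueError as e:
            log.append(f"contrast {f} skipped: {e}")
    bundle["contrasts"] = contrasts
    bundle["log"] = log
    return bundle


def report(bundle: dict, outdir) -> list[Path]:
    """Write the bundle's artifacts as CSV/JSON files; returns written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(frame: pd.DataFrame, name: str) -> None:
        p = out / name
        frame.to_csv(p)
        written.append(p)

    if "diversity" in bundle:
        div = bundle["diversity"]
        if "sites" in bundle:  # published supplementary layout carries lat/lon
            div = bundle["sites"].frame[["lat", "lon"]].join(div, how="right")
        save(div, "diversity.csv")
    if "selfing" in bundle:
        save(bundle["selfing"], "selfing.csv")
    if "bottleneck" in bundle:
        save(bundle["bottleneck"], "bottleneck.csv")
    if "predictors" in bundle:
        save(bundle["predictors"], "predictors.csv")
    for key in ("fst", "fst_linearized", "fst_mt", "geo"):
        if key in bundle:
            save(bundle[key].to_frame(), f"{key}_matrix.csv")
    if "mst" in bundle:
        save(
            pd.DataFrame(bundle["mst"], columns=["site_a", "site_b", "weight"]),
            "mst_edges.csv",
        )
    for resp, table in bundle.get("models", {}).items():
        save(table, f"models_{resp}.csv")
    if bundle.get("contrasts"):
        save(
            pd.DataFrame(
                [
                    {
                        "label": c.label,
                        "mean_within": c.mean_within,
                        "mean_rest": c.mean_rest,
                        "diff": c.observed_diff,
                        "p_one_sided": c.p_one_sided,
                        "p_two_sided": c.p_two_sided,
                        "n_perm": c.n_perm,
                    }
                    for c in bundle["contrasts"]
                ]
            ),
            "contrasts.csv",
        )
    else:
        (out / "contrasts.txt").write_text("no categorical contrasts configured\n")
        written.append(out / "contrasts.txt")
    summary = {
        "overall_fst": bundle.get("overall_fst"),
        "overall_fst_mt": bundle.get("overall_fst_mt"),
        "mantel": bundle.get("mantel"),
        "log": bundle.get("log", []),
    }
    p = out / "run_log.json"
    p.write_text(json.dumps(summary, indent=2, default=str))
    written.append(p)
    return written
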