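"""End-to-end orchestration: config-driven runs and fixture generation.

A single YAML/JSON config names the input files, the analysis parameters and
the stages to run; one master seed drives every stage (stage seeds are
derived from it), so a rerun with the same config reproduces the report
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .cognition import correlate_cognition, fisher_z_compare
from .connectivity import BundleTable, random_pattern_null
from .datasets import AnalysisConfig, load_feature_table, validate_dataset
from .exceptions import ConfigError, MbplscError
from .inference import (
    bootstrap_saliences,
    convergence_trajectory,
    monte_carlo_cv,
    nssd,
    permutation_test,
)
from .model import MBPLSC
from .simulate import SyntheticConfig, generate_bundle_table, generate_dataset

__all__ = ["ReportBundle", "run_pipeline", "make_fixture", "PRESETS"]

PRESETS = ("null", "shared_only", "shared_plus_differential", "cognition_linked")


def _canonical(obj):
    """JSON-serialisable deep copy with deterministic float formatting."""
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_canonical(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


@dataclass
class ReportBundle:
    """Machine-readable results of one pipeline run."""

    metadata: dict
    validation: dict
    model: dict
    permutation: Optional[dict] = None
    saliences: Optional[list] = None
    nssd_tables: Optional[dict] = None
    convergence: Optional[dict] = None
    cv: Optional[dict] = None
    association: Optional[list] = None
    connectivity: Optional[dict] = None

    def to_json(self) -> str:
        payload = {
            k: _canonical(v)
            for k, v in dataclasses.asdict(self).items()
            if v is not None
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "report.json"
        path.write_text(self.to_json())
        return path


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    text = Path(config).read_text()
    if str(config).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _config_hash(cfg: dict) -> str:
    # output location does not affect the results, so it is not fingerprinted
    cfg = {k: v for k, v in cfg.items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(_canonical(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run_pipeline(config, log=None) -> ReportBundle:
    """Execute the configured analysis; see the package README for the schema.

    Stage order: load → validate → fit → permutation → bootstrap → NSSD →
    convergence (optional) → CV (optional) → association → connectivity
    (optional). Any fatal validation finding aborts with a stage-named error.
    """
    log = log or (lambda msg: print(msg, file=sys.stderr))
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    stages = {
        "permutation": True,
        "bootstrap": True,
        "nssd": True,
        "convergence": False,
        "cv": False,
        "association": True,
        "connectivity": False,
    }
    stages.update(cfg.get("stages", {}))
    analysis_kw = dict(cfg.get("analysis", {}))
    analysis_kw["seed"] = seed
    aconfig = AnalysisConfig(**analysis_kw)

    log("[load] reading feature table")
    inp = cfg.get("input", {})
    try:
        ds = load_feature_table(
            inp["feature_table"], inp["schema"], on_missing=inp.get("on_missing", "error")
        )
    except KeyError as e:
        raise ConfigError(f"config input section missing key: {e}") from None

    log("[validate] checking dataset")
    report = validate_dataset(ds, aconfig)
    if not report.passed:
        raise MbplscError(f"[validate] fatal findings: {report.fatal}")

    log("[fit] assembling multiblock matrix and decomposing")
    res = MBPLSC(ds, aconfig).fit()
    mb = res.multiblock
    model_section = {
        "groups": mb.groups,
        "p": mb.p,
        "q": mb.q,
        "c_rows": mb.c_rows,
        "c_cols": mb.c_cols,
        "include_cov_cov": mb.include_cov_cov,
        "corr_method": mb.corr_method,
        "singular_values": res.singular_values,
        "xi_percent": res.xi,
        "block_contributions": res.block_contributions.to_dict(orient="index"),
        "sign_convention": "max-|entry| of each left singular vector positive",
    }

    bundle = ReportBundle(
        metadata={
            "package": "mbplsc",
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(cfg),
            "stages": stages,
            "analysis": aconfig.to_dict(),
            "dropped_participants": ds.provenance.get("dropped_participants", []),
            "sex_codings": ds.provenance.get("sex_codings", {}),
        },
        validation=json.loads(report.to_json()),
        model=model_section,
    )

    components = cfg.get("components_of_interest")
    perm = None
    if stages["permutation"]:
        log("[permutation] omnibus and per-component tests")
        perm = permutation_test(
            ds, aconfig, results=res, seed=_stage_seed(seed, "permutation")
        )
        bundle.permutation = {
            "omnibus_p": perm.omnibus_p,
            "component_p": perm.component_p,
            "n_permutations": perm.n_permutations,
            "scheme": perm.scheme,
            "observed_inertia": perm.observed_inertia,
        }
    if components is None:
        if perm is not None:
            components = perm.significant_components(aconfig.alpha)
        if not components:
            components = [0, 1] if res.n_components > 1 else [0]
    components = [int(c) for c in components]
    bundle.metadata["components_of_interest"] = components

    if stages["bootstrap"]:
        log("[bootstrap] salience confidence intervals")
        boot = bootstrap_saliences(
            ds, aconfig, results=res,
            seed=_stage_seed(seed, "bootstrap"), components=components,
        )
        bundle.saliences = boot.table.to_dict(orient="records")
        bundle.metadata["bootstrap"] = {
            "n_iterations": boot.n_iterations,
            "n_discarded": boot.n_discarded,
            "unreliable": boot.unreliable,
        }
    else:
        boot = None

    if stages["nssd"]:
        log("[nssd] between-group salience differences")
        bundle.nssd_tables = {
            f"LV{c + 1}": nssd(res, c).to_dict() for c in components
        }

    if stages["convergence"]:
        log("[convergence] salience trajectories over sample size")
        traj = convergence_trajectory(
            ds, aconfig, results=res, components=components,
            seed=_stage_seed(seed, "convergence"),
        )
        bundle.convergence = {
            f"LV{c + 1}": {
                "n": traj.n_grid,
                "mean_abs_diff": traj.mean_trajectory(c).to_numpy(),
            }
            for c in components
        }

    if stages["cv"]:
        log("[cv] Monte Carlo cross-validation")
        bundle.cv = {}
        for c in components:
            cv = monte_carlo_cv(
                ds, aconfig, results=res, component=c, seed=_stage_seed(seed, f"cv{c}")
            )
            bundle.cv[f"LV{c + 1}"] = {
                "summary": cv.summary.reset_index().to_dict(orient="records"),
                "n_splits": cv.n_splits,
                "train_fraction": cv.train_fraction,
            }

    if stages["association"]:
        if ds.cognition_names:
            log("[association] cognition vs latent scores")
            assoc = correlate_cognition(res.scores(), ds, components, aconfig)
            bundle.association = assoc.to_dict(orient="records")
            if len(ds.group_labels) == 2:
                g1, g2 = ds.group_labels
                comparisons = []
                for (comp, cogn, side), grp in assoc.groupby(
                    ["component", "cognition", "score_block"]
                ):
                    r1 = grp.loc[grp["group"] == g1]
                    r2 = grp.loc[grp["group"] == g2]
                    if len(r1) and len(r2):
                        z, p = fisher_z_compare(
                            float(r1["coefficient"].iloc[0]), int(r1["n"].iloc[0]),
                            float(r2["coefficient"].iloc[0]), int(r2["n"].iloc[0]),
                        )
                        comparisons.append(
                            {"component": int(comp), "cognition": cogn,
                             "score_block": side, "z": z, "p": p}
                        )
                bundle.metadata["fisher_z_comparisons"] = comparisons
        else:
            log("[association] skipped: no cognition columns")

    if stages["connectivity"]:
        log("[connectivity] random-pattern null")
        if "bundle_table" not in inp:
            raise ConfigError("connectivity stage requires input.bundle_table")
        bt = BundleTable.from_tsv(inp["bundle_table"])
        pat = cfg.get("pattern", {})
        if "regions" in pat and "tracts" in pat:
            regions, tracts = pat["regions"], pat["tracts"]
        elif boot is not None and components:
            comp = components[0] if "component" not in pat else int(pat["component"])
            t = boot.table
            sig = t[t["significant"]]
            regions = sorted(
                set(sig[(sig["margin"] == "row") & (sig["block"] == "gm")
                        & (sig["component"] == comp)]["variable"])
                & set(bt.region_universe)
            )
            tracts = sorted(
                set(sig[(sig["margin"] == "col") & (sig["block"] == "wm")
                        & (sig["component"] == comp)]["variable"])
                & set(bt.tract_universe)
            )
        else:
            raise ConfigError(
                "connectivity stage needs pattern.regions/tracts or a bootstrap stage"
            )
        if regions and tracts:
            test = random_pattern_null(
                bt, regions, tracts,
                n_permutations=int(pat.get("n_permutations", aconfig.n_permutations)),
                seed=_stage_seed(seed, "connectivity"),
            )
            bundle.connectivity = test.to_dict() | {
                "regions": list(regions), "tracts": list(tracts)
            }
        else:
            bundle.connectivity = {
                "note": "empty pattern after intersecting with universes",
                "regions": list(regions), "tracts": list(tracts),
            }

    outdir = cfg.get("output_dir")
    if outdir:
        path = bundle.write(outdir)
        _write_tables(outdir, res, bundle)
        log(f"[done] report written to {path}")
    return bundle


def _write_tables(outdir, res, bundle: ReportBundle):
    import pandas as pd

    outdir = Path(outdir)
    sal = []
    for g in res.multiblock.groups:
        df = res.gm_saliences(g)
        df.insert(0, "group", g)
        df.insert(1, "block", "gm")
        sal.append(df.reset_index(names="variable"))
        if res.multiblock.c_rows:
            dc = res.cov_row_saliences(g)
            dc.insert(0, "group", g)
            dc.insert(1, "block", "cov")
            sal.append(dc.reset_index(names="variable"))
    wm = res.wm_saliences()
    wm.insert(0, "group", "shared")
    wm.insert(1, "block", "wm")
    sal.append(wm.reset_index(names="variable"))
    if res.multiblock.c_cols:
        cc = res.cov_col_saliences()
        cc.insert(0, "group", "shared")
        cc.insert(1, "block", "cov")
        sal.append(cc.reset_index(names="variable"))
    pd.concat(sal, ignore_index=True).to_csv(outdir / "saliences.tsv", sep="\t",
                                             index=False)
    if bundle.saliences is not None:
        pd.DataFrame(bundle.saliences).to_csv(outdir / "salience_ci.tsv", sep="\t",
                                              index=False)
    if bundle.association is not None:
        pd.DataFrame(bundle.association).to_csv(outdir / "association.tsv", sep="\t",
                                                index=False)


def make_fixture(outdir, preset: str = "shared_plus_differential", seed: int = 0,
                 n_per_group: int = 71, p: int = 68, q: int = 48) -> dict:
    """Write a synthetic feature table, schema, bundle table and ground truth.

    Presets: 'null' (no couplings), 'shared_only' (one shared component),
    'shared_plus_differential' (shared + opposite-polarity differential,
    clean latent structure), 'cognition_linked' (adds covariate structure
    and the patient-group cognition link).
    """
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose from {PRESETS}")
    base = SyntheticConfig(n_per_group=n_per_group, p=p, q=q, seed=seed)
    if preset == "null":
        cfg = base.replace(shared_effect=0.0, diff_effect=0.0,
                           cognition_link=(0.0, 0.0), age_effect=0.0,
                           sex_tiv_effect=0.0)
    elif preset == "shared_only":
        cfg = base.replace(diff_effect=0.0, cognition_link=(0.0, 0.0),
                           age_effect=0.0, sex_tiv_effect=0.0)
    elif preset == "shared_plus_differential":
        cfg = base.replace(cognition_link=(0.0, 0.0), age_effect=0.0,
                           sex_tiv_effect=0.0)
    else:  # cognition_linked: full structure
        cfg = base

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds, gt = generate_dataset(cfg)
    ds.write(outdir / "features.csv", schema_path=outdir / "schema.yaml")
    (outdir / "ground_truth.json").write_text(gt.to_json())

    rng = np.random.default_rng(seed + 17)
    planted_regions = sorted(rng.choice(p, size=min(8, p), replace=False).tolist())
    planted_tracts = sorted(rng.choice(q, size=min(5, q), replace=False).tolist())
    enrich = 1.0 if preset == "null" else 20.0
    bt, pattern = generate_bundle_table(
        n_regions=p, n_tracts=q, planted_regions=planted_regions,
        planted_tracts=planted_tracts, enrichment=enrich, seed=seed + 18,
        region_labels=ds.gm_names, tract_labels=ds.wm_names,
    )
    bt.to_tsv(outdir / "bundles.tsv")
    (outdir / "pattern.json").write_text(
        json.dumps({"regions": pattern[0], "tracts": pattern[1],
                    "enrichment": enrich}, indent=2)
    )
    return {
        "features": str(outdir / "features.csv"),
        "schema": str(outdir / "schema.yaml"),
        "bundles": str(outdir / "bundles.tsv"),
        "ground_truth": str(outdir / "ground_truth.json"),
        "pattern": str(outdir / "pattern.json"),
        "preset": preset,
        "config": dataclasses.asdict(cfg),
    }
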