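"""End-to-end pipeline: trajectories -> kinematics -> cycles -> scaling ->
normalized species traits -> correlations/PCA -> phylogenetic signal.

Every stage writes plain-text outputs (CSV/TSV + Newick + YAML) into the
run directory together with a manifest and a log, and can be re-run from
the previous stage's files. All randomness flows from the single seed in
the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinematics as kin
from . import multivariate, ontogeny, phylo, pulses, synthetic

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("pulsekin")

DEFAULT_TRAITS = [
    "f_mean", "u_mean", "re_mean", "P_freq", "P_time", "P_dist",
    "C_time", "C_dist", "R_time", "R_dist", "I_time", "I_dist", "PER",
]


@dataclass
class PipelineConfig:
    output_dir: str = "pulsekin_run"
    seed: int = 0
    # synthetic study
    n_species: int = 5
    diameters_cm: tuple = (0.5, 1.5, 4.0)
    # optional real inputs: directory of trajectory CSVs overrides synthesis
    trajectories_dir: str | None = None
    # analysis options
    smooth_window: int = 0
    resample_dt: float | None = None
    viscosity: float | None = None
    prominence_frac: float = 0.25
    min_separation_frac: float = 0.5
    # downstream
    traits: tuple = tuple(DEFAULT_TRAITS)
    pca_columns: tuple | None = None
    tree_path: str | None = None  # None -> packaged 17-taxon example tree
    n_perm: int = 1000
    ace_trait: str | None = None  # None -> first trait with finite values
    run_physig: bool = True

    def validate(self) -> None:
        if self.n_perm < 99:
            raise ValueError("config: n_perm must be >= 99")
        if self.trajectories_dir is not None and not Path(self.trajectories_dir).is_dir():
            raise ValueError(f"config: trajectories_dir {self.trajectories_dir!r} not found")
        if self.run_physig and self.tree_path is not None and not Path(self.tree_path).is_file():
            raise ValueError(f"config: tree file {self.tree_path!r} not found")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["diameters_cm"] = list(self.diameters_cm)
        d["traits"] = list(self.traits)
        d["pca_columns"] = list(self.pca_columns) if self.pca_columns else None
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _load_trajectories(cfg: PipelineConfig, outdir: Path) -> list[kin.TrajectorySequence]:
    if cfg.trajectories_dir is not None:
        paths = sorted(Path(cfg.trajectories_dir).glob("*.csv"))
        trajs = [kin.TrajectorySequence.from_csv(p) for p in paths]
        log.info("loaded %d trajectories from %s", len(trajs), cfg.trajectories_dir)
        return trajs
    tree = phylo.load_default_tree() if cfg.tree_path is None else phylo.parse_newick(
        Path(cfg.tree_path).read_text()
    )
    tips = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    rng = np.random.default_rng(cfg.seed)
    chosen = list(rng.choice(tips, size=min(cfg.n_species, len(tips)), replace=False))
    trajs, truth = synthetic.generate_study(
        chosen, diameters_cm=cfg.diameters_cm, seed=cfg.seed
    )
    truth.to_csv(outdir / "ground_truth_params.csv", index=False)
    pd.concat([t.to_frame() for t in trajs]).to_csv(outdir / "trajectories.csv", index=False)
    log.info("simulated %d trajectories for %d species", len(trajs), len(chosen))
    return trajs


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict[str, str] = {}

    def _emit(name: str, fname: str) -> None:
        manifest[name] = fname
        log.info("wrote %s", fname)

    try:
        cfg.to_yaml(outdir / "config.yaml")
        _emit("config", "config.yaml")

        trajs = _load_trajectories(cfg, outdir)
        if (outdir / "trajectories.csv").exists():
            _emit("trajectories", "trajectories.csv")

        # kinematics + cycle segmentation per sequence
        kin_rows, cyc_rows, seq_rows = [], [], []
        for traj in trajs:
            ks = kin.compute_kinematics(
                traj,
                viscosity=cfg.viscosity,
                resample_dt=cfg.resample_dt,
                smooth_window=cfg.smooth_window,
            )
            kf = ks.to_frame()
            kf.insert(0, "individual", traj.individual)
            kf.insert(0, "species", traj.species)
            kin_rows.append(kf)
            metrics, cycles = pulses.analyze_sequence(
                ks,
                prominence_frac=cfg.prominence_frac,
                min_separation_frac=cfg.min_separation_frac,
                smooth_window=cfg.smooth_window,
            )
            cf = pulses.cycles_frame(cycles)
            if len(cf):
                cf.insert(0, "individual", traj.individual)
                cf.insert(0, "species", traj.species)
            cyc_rows.append(cf)
            row = {"species": traj.species, "individual": traj.individual}
            row.update(kin.sequence_means(ks))
            row.update(metrics.to_dict())
            row["diameter_cm"] = metrics.reference_diameter
            seq_rows.append(row)
            log.info(
                "sequence %s: %d cycles (%d velocity-only fallbacks)",
                traj.individual, metrics.n_pulses,
                metrics.extras.get("n_fallback_velocity_only", 0),
            )
        pd.concat(kin_rows).to_csv(outdir / "kinematics.csv", index=False)
        _emit("kinematics", "kinematics.csv")
        pd.concat([c for c in cyc_rows if len(c)]).to_csv(outdir / "cycles.csv", index=False)
        _emit("cycles", "cycles.csv")
        seq_df = pd.DataFrame(seq_rows)
        seq_df.to_csv(outdir / "sequence_metrics.csv", index=False)
        _emit("sequence_metrics", "sequence_metrics.csv")

        # ontogenetic scaling + size normalization
        traits = [t for t in cfg.traits if t in seq_df and seq_df[t].notna().sum() >= 4]
        table, fits = ontogeny.species_trait_table(seq_df, traits)
        fit_rows = [
            {"trait": tr, "family": f.family, "equation": f.equation(),
             "r2": f.r2, "p": f.p, "df": f.df, "bic": f.bic}
            for tr, f in fits.items()
        ]
        pd.DataFrame(fit_rows).to_csv(outdir / "model_fits.tsv", sep="\t", index=False)
        _emit("model_fits", "model_fits.tsv")
        table.to_csv(outdir / "species_traits.csv")
        _emit("species_traits", "species_traits.csv")

        # correlations + PCA
        r, p = multivariate.pearson_matrix(table)
        r.to_csv(outdir / "pearson_r.csv")
        p.to_csv(outdir / "pearson_p.csv")
        _emit("pearson", "pearson_r.csv")
        pca_cols = [c for c in (cfg.pca_columns or table.columns) if c in table]
        res = multivariate.pca(table[pca_cols])
        res.loadings.to_csv(outdir / "pca_loadings.csv")
        res.scores.to_csv(outdir / "pca_scores.csv")
        pd.DataFrame(
            {"component": res.loadings.columns,
             "explained_variance_fraction": res.explained_variance_ratio}
        ).to_csv(outdir / "pca_variance.csv", index=False)
        _emit("pca", "pca_variance.csv")

        # phylogenetic signal + ancestral states
        if cfg.run_physig:
            tree = (
                phylo.load_default_tree()
                if cfg.tree_path is None
                else phylo.parse_newick(Path(cfg.tree_path).read_text())
            )
            tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
            common = sorted(tips & set(table.index))
            if len(common) >= 3:
                sub = phylo.prune_to_taxa(tree, common) if len(common) < len(tips) else tree
                C = phylo.phylo_vcv(sub)
                sig_rows = []
                for k_i, tr in enumerate(table.columns):
                    vals = table[tr].reindex(common).dropna()
                    if len(vals) < 3 or np.ptp(vals.to_numpy()) == 0:
                        continue
                    Csub = C.loc[vals.index, vals.index]
                    res_k = phylo.blomberg_k_test(
                        Csub, vals, n_perm=cfg.n_perm,
                        seed=int(np.random.default_rng(cfg.seed + k_i).integers(2**31 - 1)),
                    )
                    sig_rows.append({"Variable": tr, "K": res_k.K, "p": res_k.p})
                pd.DataFrame(sig_rows).to_csv(outdir / "phylosignal.tsv", sep="\t", index=False)
                _emit("phylosignal", "phylosignal.tsv")

                ace_trait = cfg.ace_trait or (sig_rows[0]["Variable"] if sig_rows else None)
                if ace_trait is not None:
                    vals = table[ace_trait].reindex(common).dropna()
                    sub2 = phylo.prune_to_taxa(tree, list(vals.index))
                    amap = phylo.ancestral_states_ml(sub2, vals)
                    amap.node_states.rename_axis("node").reset_index().to_csv(
                        outdir / "ancestral_states.tsv", sep="\t", index=False
                    )
                    amap.edge_grid.to_csv(outdir / "ancestral_edges.tsv", sep="\t", index=False)
                    _emit("ancestral_states", "ancestral_states.tsv")
            else:
                log.warning("fewer than 3 species match tree tips; physig skipped")

        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.info("pipeline complete: %d outputs", len(manifest))
        return manifest
    except Exception:
        log.exception("pipeline failed; partial outputs preserved in %s", outdir)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
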