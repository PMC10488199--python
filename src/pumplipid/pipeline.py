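"""End-to-end orchestration: generate or ingest data, run every analysis
stage, and emit a joined, checksummed report.

A run is driven by a single YAML (or dict) configuration. Stages execute in
dependency order (traces -> stats; solubilization; membrane; conservation);
a failing stage stops its dependents but completed outputs are kept, and the
manifest is written last. Identical config + seed reproduces identical
checksums for all deterministic stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import group_stats as gs
from . import io as plio
from . import kinetics as kin
from . import membrane as mem
from . import synthetic as syn
from .errors import ConfigurationError

__all__ = ["RunManifest", "default_config", "load_config", "validate", "run"]

log = logging.getLogger("pumplipid")


def default_config(output_dir: str = "results/run", seed: int = 1) -> dict:
    """A small all-generator demo configuration that exercises every stage."""
    return {
        "seed": seed,
        "output_dir": output_dir,
        "stages": {
            "traces": True,
            "stats": True,
            "solubilization": True,
            "membrane": True,
            "conservation": True,
        },
        "kinetics": {
            "window_s": 30.0,
            "reference": "PC",
            "conditions": {"PC": 1.0, "PC:PS": 5.3, "PC:PG": 2.4},
            "n_replicates": 3,
            "manifest": None,
            "trace": {
                "t_mg": 30.0,
                "t_cccp": 500.0,
                "t_end": 560.0,
                "dt": 0.2,
                "rate": 1.0e-3,
                "plateau": 0.25,
                "recovery": 0.95,
                "noise_sd": 0.003,
            },
        },
        "solubilization": {
            "top": 1000.0,
            "bottom": 100.0,
            "v50": 12.0,
            "slope": 2.0,
            "noise_sd": 10.0,
            "x_min": 2.0,
            "x_max": 25.0,
            "n_points": 25,
        },
        "membrane": {
            "trajectory": None,
            "topology": None,
            "cutoff": mem.CONTACT_CUTOFF_NM,
            "spacing_2d": 0.1,
            "spacing_3d": 0.25,
            "min_enrichment": 2.0,
            "species_focus": "PS",
            "label_threshold": mem.LABEL_THRESHOLD,
            "highlight_threshold": mem.HIGHLIGHT_THRESHOLD,
            "generator": {
                "box": [10.0, 10.0, 10.0],
                "n_lipids_total": 150,
                "composition": {"PS": 0.10, "PC": 0.90},
                "n_frames": 400,
                "diffusion_step": 0.4,
                "hotspot": {"helix": 0, "leaflet": "upper", "strength": 25.0, "radius": 0.7},
            },
        },
        "conservation": {
            "alignment": None,  # packaged synthetic fixture
            "format": "fasta",
            "reference": "AHA2_SYN",
            "contact_residues": None,  # fixture default
        },
        "stats": {"alpha": 0.05},
    }


def load_config(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark else ""
        raise ConfigurationError(f"cannot parse {path}{where}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path} must contain a mapping")
    return cfg


def validate(config: Mapping[str, Any] | str | Path) -> list[str]:
    """Return every violation found (empty list means runnable)."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    v: list[str] = []

    def positive(section: str, key: str, value) -> None:
        if not isinstance(value, (int, float)) or value <= 0:
            v.append(f"{section}.{key} must be a positive number (got {value!r})")

    if "output_dir" not in config:
        v.append("output_dir is required")
    if not isinstance(config.get("seed", 0), int) or config.get("seed", 0) < 0:
        v.append("seed must be a non-negative integer")

    stages = config.get("stages", {})
    k = config.get("kinetics", {})
    if stages.get("traces"):
        positive("kinetics", "window_s", k.get("window_s", 30.0))
        manifest = k.get("manifest")
        if manifest is not None:
            if not Path(manifest).exists():
                v.append(f"kinetics.manifest path does not exist: {manifest}")
        else:
            conds = k.get("conditions", {})
            if not conds:
                v.append("kinetics.conditions must be non-empty when no manifest is given")
            ref = k.get("reference")
            if ref is not None and conds and ref not in conds:
                v.append(f"kinetics.reference {ref!r} not among conditions")
            if k.get("n_replicates", 1) < 1:
                v.append("kinetics.n_replicates must be >= 1")

    s = config.get("solubilization", {})
    if stages.get("solubilization"):
        if s.get("slope", 1.0) == 0:
            v.append("solubilization.slope must be nonzero")
        if s.get("n_points", 25) < 5:
            v.append("solubilization.n_points must be >= 5")

    m = config.get("membrane", {})
    if stages.get("membrane"):
        for key in ("cutoff", "spacing_2d", "spacing_3d", "min_enrichment"):
            positive("membrane", key, m.get(key, 1.0))
        for key in ("label_threshold", "highlight_threshold"):
            positive("membrane", key, m.get(key, 0.05))
        traj = m.get("trajectory")
        if traj is not None:
            paths = traj if isinstance(traj, list) else [traj]
            for p in paths:
                if not Path(p).exists():
                    v.append(f"membrane.trajectory path does not exist: {p}")
            top = m.get("topology")
            if top is None:
                v.append("membrane.topology is required with an external trajectory")
            elif not Path(top).exists():
                v.append(f"membrane.topology path does not exist: {top}")
        elif not m.get("generator"):
            v.append("membrane needs either a trajectory or a generator block")

    c = config.get("conservation", {})
    if stages.get("conservation"):
        if c.get("format", "fasta") not in ("fasta", "clustal"):
            v.append(f"conservation.format must be fasta or clustal (got {c.get('format')!r})")
        aln = c.get("alignment")
        if aln is not None and not Path(aln).exists():
            v.append(f"conservation.alignment path does not exist: {aln}")

    alpha = config.get("stats", {}).get("alpha", 0.05)
    if stages.get("stats") and not (0 < alpha < 1):
        v.append(f"stats.alpha must be in (0, 1) (got {alpha!r})")
    return v


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    log_path: str = ""

    def to_json_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "stages": self.stages,
            "log": self.log_path,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sub_seed(root: int, *key: int) -> int:
    return int(np.random.SeedSequence(root, spawn_key=key).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# stages (each returns {output_name: Path} and may stash results in `shared`)


def _stage_traces(config, outdir: Path, shared: dict) -> dict[str, Path]:
    k = config["kinetics"]
    window = float(k.get("window_s", 30.0))
    rows = []
    rates: dict[str, list[kin.PumpRate]] = {}
    if k.get("manifest"):
        man = pd.read_csv(k["manifest"], sep="\t")
        for r in man.itertuples():
            trace = plio.read_trace_csv(r.trace_path)
            pr = kin.analyze_trace(trace, window_s=window)
            rates.setdefault(r.condition, []).append(pr)
            rows.append((r.condition, r.replicate, pr.rate, pr.active, pr.r_squared))
    else:
        base = dict(k.get("trace", {}))
        root = int(config.get("seed", 0))
        for ci, (cond, mult) in enumerate(k["conditions"].items()):
            for rep in range(int(k.get("n_replicates", 3))):
                cfg = syn.TraceGenConfig(
                    **{**base, "rate": base.get("rate", 5e-4) * float(mult),
                       "seed": _sub_seed(root, 0, ci, rep)}
                )
                pr = kin.analyze_trace(syn.gen_acma_trace(cfg), window_s=window)
                rates.setdefault(cond, []).append(pr)
                rows.append((cond, rep, pr.rate, pr.active, pr.r_squared))
    per_trace = pd.DataFrame(
        rows, columns=["condition", "replicate", "rate_per_s", "active", "r_squared"]
    )
    rates_path = outdir / "rates.tsv"
    per_trace.to_csv(rates_path, sep="\t", index=False)

    reference = k.get("reference") or next(iter(rates))
    folds = kin.fold_changes(rates, reference)
    folds_path = outdir / "folds.tsv"
    pd.DataFrame(
        [(c, f) for c, f in folds.items()], columns=["condition", "fold_vs_" + reference]
    ).to_csv(folds_path, sep="\t", index=False)
    shared["rates"] = rates
    shared["per_trace"] = per_trace
    log.info("traces: %d traces, folds vs %s: %s", len(per_trace), reference,
             {c: round(f, 2) for c, f in folds.items()})
    return {"rates": rates_path, "folds": folds_path}


def _stage_stats(config, outdir: Path, shared: dict) -> dict[str, Path]:
    alpha = float(config.get("stats", {}).get("alpha", 0.05))
    groups = {
        cond: [p.rate for p in prs if p.active]
        for cond, prs in shared["rates"].items()
    }
    groups = {c: v for c, v in groups.items() if len(v) >= 2}
    f, p = gs.anova_oneway(groups)
    tukey = gs.tukey_hsd(groups, alpha=alpha)
    letters = gs.letter_display(tukey)
    pairs_path = outdir / "tukey_pairs.tsv"
    t = tukey.table.copy()
    t["tier"] = [gs.significance_tier(x) for x in t.p_adj]
    t.to_csv(pairs_path, sep="\t", index=False)
    letters_path = outdir / "letters.tsv"
    box_rows = []
    for cond, vals in groups.items():
        b = gs.boxplot_summary(vals)
        box_rows.append(
            (cond, letters[cond], b.median, b.q25, b.q75, b.whisker_low, b.whisker_high)
        )
    pd.DataFrame(
        box_rows,
        columns=["condition", "letters", "median", "q25", "q75", "whisker_low", "whisker_high"],
    ).to_csv(letters_path, sep="\t", index=False)
    anova_path = outdir / "anova.tsv"
    pd.DataFrame([(f, p, gs.significance_tier(p))], columns=["F", "p", "tier"]).to_csv(
        anova_path, sep="\t", index=False
    )
    log.info("stats: ANOVA F=%.3g p=%.3g; letters %s", f, p, letters)
    return {"anova": anova_path, "tukey_pairs": pairs_path, "letters": letters_path}


def _stage_solubilization(config, outdir: Path, shared: dict) -> dict[str, Path]:
    s = config["solubilization"]
    x = np.linspace(float(s["x_min"]), float(s["x_max"]), int(s["n_points"]))
    series = syn.gen_solubilization_series(
        float(s["top"]), float(s["bottom"]), float(s["v50"]), float(s["slope"]),
        x, noise_sd=float(s.get("noise_sd", 0.0)),
        seed=_sub_seed(int(config.get("seed", 0)), 1),
    )
    fit = kin.fit_boltzmann(series)
    path = outdir / "boltzmann_fit.tsv"
    pd.DataFrame(
        [(fit.top, fit.bottom, fit.v50, fit.slope, fit.rss, fit.converged)],
        columns=["top", "bottom", "v50_mM", "slope_mM", "rss", "converged"],
    ).to_csv(path, sep="\t", index=False)
    log.info("solubilization: V50 = %.3f mM (true %.3f)", fit.v50, float(s["v50"]))
    return {"boltzmann_fit": path}


def _stage_membrane(config, outdir: Path, shared: dict) -> dict[str, Path]:
    m = config["membrane"]
    outputs: dict[str, Path] = {}
    if m.get("trajectory") is not None:
        traj, topology = plio.read_trajectory(m["trajectory"], m["topology"])
        truth = None
        leaflet_counts = None
    else:
        g = m["generator"]
        gen_cfg = syn.MembraneGenConfig(
            box=tuple(g.get("box", (13.0, 13.0, 10.0))),
            n_lipids_total=int(g.get("n_lipids_total", 524)),
            composition=dict(g.get("composition", {"PS": 0.10, "PC": 0.90})),
            n_frames=int(g.get("n_frames", 1000)),
            diffusion_step=float(g.get("diffusion_step", 0.2)),
            seed=_sub_seed(int(config.get("seed", 0)), 2),
        )
        hs = g.get("hotspot")
        if hs:
            residues = syn.helix_interface_residues(
                gen_cfg, int(hs.get("helix", 0)), hs.get("leaflet", "upper")
            )
            gen_cfg = syn.MembraneGenConfig(
                **{
                    **gen_cfg.__dict__,
                    "hotspots": (
                        syn.HotspotSpec(
                            residue_ids=residues,
                            species=hs.get("species", m.get("species_focus", "PS")),
                            strength=float(hs.get("strength", 25.0)),
                            radius=float(hs.get("radius", 0.7)),
                        ),
                    ),
                }
            )
        traj, topology, truth = syn.gen_membrane_trajectory(gen_cfg)
        leaflet_counts = truth.leaflet_counts
        plio.write_topology_tsv(topology, outdir / "topology.tsv")
        plio.write_ground_truth(truth, outdir / "ground_truth.json")
        outputs["topology"] = outdir / "topology.tsv"
        outputs["ground_truth"] = outdir / "ground_truth.json"

    aligned = mem.align_frames(traj, topology)
    profile = mem.contact_probabilities(traj, topology, cutoff=float(m["cutoff"]))
    contacts_path = outdir / "contact_probabilities.tsv"
    profile.to_frame().to_csv(contacts_path, sep="\t", index=False)
    outputs["contacts"] = contacts_path

    species = m.get("species_focus", "PS")
    if leaflet_counts is None:
        counts0 = mem.assign_leaflets(traj.coords[0], topology)
        leaflet_counts = {
            lf: {
                sp: int(
                    sum(
                        1
                        for mid, l in counts0.items()
                        if l == lf
                        and topology.lipid_species[
                            np.searchsorted(topology.lipid_ids, mid)
                        ]
                        == sp
                    )
                )
                for sp in topology.species
            }
            for lf in ("upper", "lower")
        }
    sites_all = []
    for leaflet in ("upper", "lower"):
        dmap = mem.density_map_2d(
            aligned, topology, species, leaflet, spacing=float(m["spacing_2d"])
        )
        enr = mem.enrichment_map(dmap, leaflet_counts)
        plio.write_density2d(dmap, outdir / f"density2d_{species}_{leaflet}.tsv")
        plio.write_density2d(enr, outdir / f"enrichment2d_{species}_{leaflet}.tsv")
        outputs[f"density2d_{leaflet}"] = outdir / f"density2d_{species}_{leaflet}.tsv"
        outputs[f"enrichment2d_{leaflet}"] = outdir / f"enrichment2d_{species}_{leaflet}.tsv"
        sites_all.extend(
            mem.find_sites(
                enr,
                profile,
                mem.residue_positions(aligned, topology),
                min_enrichment=float(m["min_enrichment"]),
                prob_threshold=float(m.get("highlight_threshold", 0.05)),
            )
        )
    sites_path = outdir / "sites.tsv"
    pd.DataFrame(
        [
            (
                s.label,
                s.leaflet,
                s.species,
                s.centroid[0],
                s.centroid[1],
                s.peak_enrichment,
                ",".join(map(str, s.residues)),
            )
            for s in sites_all
        ],
        columns=["label", "leaflet", "species", "x_nm", "y_nm", "peak_enrichment", "residues"],
    ).to_csv(sites_path, sep="\t", index=False)
    outputs["sites"] = sites_path

    grid = mem.density_grid_3d(
        aligned, topology, species, beads="headgroup", spacing=float(m["spacing_3d"])
    )
    dx_path = outdir / f"density3d_{species}_headgroup.dx"
    plio.write_dx(grid, dx_path)
    outputs["density3d"] = dx_path
    shared["profile"] = profile
    shared["sites"] = sites_all
    log.info(
        "membrane: %d frames, %d sites called, max %s contact probability %.3f",
        traj.n_frames, len(sites_all), species, profile.probabilities.max(),
    )
    return outputs


def packaged_alignment_path() -> Path:
    return Path(resources.files("pumplipid.data") / "synthetic_ptype_sites.fasta")


def _stage_conservation(config, outdir: Path, shared: dict) -> dict[str, Path]:
    c = config["conservation"]
    path = c.get("alignment") or packaged_alignment_path()
    aln = cons.read_alignment(path, c.get("format", "fasta"))
    reference = c.get("reference", "AHA2_SYN")
    residues = c.get("contact_residues")
    if residues is None:
        from .data import SYNTHETIC_CONTACT_RESIDUES

        residues = SYNTHETIC_CONTACT_RESIDUES
    report = cons.site_report(aln, reference, residues)
    rep_path = outdir / "conservation_report.tsv"
    report.to_csv(rep_path, sep="\t", index=False)
    log.info(
        "conservation: %d/%d contact residues fully conserved",
        int(report.identical_in_all.sum()), len(report),
    )
    return {"conservation_report": rep_path}


_STAGES = [
    ("traces", _stage_traces, ()),
    ("stats", _stage_stats, ("traces",)),
    ("solubilization", _stage_solubilization, ()),
    ("membrane", _stage_membrane, ()),
    ("conservation", _stage_conservation, ()),
]


def run(config: Mapping[str, Any] | str | Path) -> RunManifest:
    """Validate, execute all enabled stages and write the manifest."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    config = copy.deepcopy(dict(config))
    violations = validate(config)
    if violations:
        raise ConfigurationError("invalid config: " + "; ".join(violations))

    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    from . import __version__

    manifest = RunManifest(config_hash=cfg_hash, version=__version__, log_path=str(log_path))
    shared: dict = {}
    failed: set[str] = set()
    enabled = config.get("stages", {})
    try:
        for name, fn, deps in _STAGES:
            if not enabled.get(name):
                manifest.stages[name] = {"status": "skipped"}
                continue
            if any(d in failed or not enabled.get(d) for d in deps):
                manifest.stages[name] = {"status": "blocked", "blocked_on": list(deps)}
                failed.add(name)
                continue
            log.info("stage %s: start (config %s)", name,
                     json.dumps(config.get(name if name != "traces" else "kinetics", {}),
                                default=str))
            try:
                outputs = fn(config, outdir, shared)
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                manifest.stages[name] = {"status": "failed", "error": str(exc)}
                failed.add(name)
                continue
            manifest.stages[name] = {
                "status": "ok",
                "outputs": {
                    k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()
                },
            }
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest.to_json_dict(), indent=1))
        log.removeHandler(handler)
        handler.close()
    return manifest
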