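"""End-to-end orchestration of the analysis stages from one YAML config.

A run config names the stages to execute with their parameters; defaults
follow the study settings (5 ML restarts, AIC evidence ratio 2.7, Ks
window 0.05–5, clade-split threshold 5, up to 9 mixture components,
1000 bootstrap replicates at alpha 0.01, Fisher alpha 0.05).  Each run
writes a manifest recording the resolved config, seeds, input checksums
and per-stage row counts; re-running with unchanged inputs skips stages
whose recorded input checksums still match.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    parse_newick,
    read_annotations,
    read_blast_tab,
    read_codon_fasta,
    read_counts_table,
    FamilyCounts,
)
from .enrichment import enrich_terms
from .gmm_peaks import filter_ks, peak_confidence_intervals, select_k_bic, select_k_bootstrap
from .ks_engine import CodonPair, gy94_fit, ng86_ks
from .nupt import color_links, summarize_nupt, write_circos_links
from .synthetic import split_seed
from .turnover import compare_models, classify_family, fit_turnover

log = logging.getLogger("plastburst")

DEFAULTS = {
    "restarts": 5,
    "evidence_ratio": 2.7,
    "ks_window": [0.05, 5.0],
    "split_threshold": 5.0,
    "kmax": 9,
    "B": 1000,
    "alpha": 0.01,
    "fisher_alpha": 0.05,
}

KNOWN_STAGE_KEYS = {
    "turnover": {"tree", "counts", "model", "foreground", "restarts", "per_family"},
    "ks": {"pairs", "method", "restarts"},
    "peaks": {"ks", "weights_column", "select", "kmax", "B", "alpha", "ci_B"},
    "nupt": {"hits", "genome_bp", "merge", "scaffold_lens", "plastid_bp"},
    "enrich": {"subset", "annotations", "universe", "alpha"},
}


class ConfigError(ValueError):
    pass


def load_config(path) -> Dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    top_known = {"seed", "outdir", "stages"} | set(DEFAULTS)
    unknown = set(cfg) - top_known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    stages = cfg.get("stages", {})
    for name, params in stages.items():
        if name not in KNOWN_STAGE_KEYS:
            raise ConfigError(f"unknown stage {name!r}")
        bad = set(params or {}) - KNOWN_STAGE_KEYS[name]
        if bad:
            raise ConfigError(f"stage {name!r}: unknown keys {sorted(bad)}")
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config_path, outdir: Optional[str] = None) -> Dict:
    """Execute the configured stages in order; returns the manifest."""
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 0))
    out = Path(outdir or cfg.get("outdir", "plastburst_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text()).get("stages", {})

    manifest: Dict = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": {},
        "status": "ok",
    }
    order = ["turnover", "ks", "peaks", "nupt", "enrich"]
    try:
        for name in order:
            if name not in cfg.get("stages", {}):
                continue
            params = cfg["stages"][name] or {}
            inputs = _stage_inputs(name, params)
            checksums = {p: _sha256(p) for p in inputs}
            prev = previous.get(name)
            if prev and prev.get("checksums") == checksums and prev.get("status") == "ok":
                log.info("stage=%s cache hit, skipped", name)
                entry = dict(prev)
                entry["cached"] = True
                manifest["stages"][name] = entry
                continue
            t0 = time.time()
            rows = _STAGE_FNS[name](params, cfg, seed, out)
            manifest["stages"][name] = {
                "status": "ok",
                "rows": rows,
                "seconds": round(time.time() - t0, 3),
                "seed": split_seed(seed, name),
                "checksums": checksums,
                "cached": False,
            }
            log.info("stage=%s rows=%d seed=%d", name, rows, split_seed(seed, name))
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failure"] = {"stage": name, "error": str(exc)}
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
        raise
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _stage_inputs(name: str, params: Dict) -> List[str]:
    keys = {
        "turnover": ["tree", "counts"],
        "ks": ["pairs"],
        "peaks": ["ks"],
        "nupt": ["hits", "scaffold_lens"],
        "enrich": ["subset", "annotations", "universe"],
    }[name]
    return [params[k] for k in keys if params.get(k)]


# ---------------------------------------------------------------------------
# stage runners (thin wrappers over the library; each returns a row count)
# ---------------------------------------------------------------------------

def _run_turnover(params, cfg, seed, out: Path) -> int:
    tree = parse_newick(Path(params["tree"]).read_text(), species_tree=True)
    counts = read_counts_table(params["counts"])
    restarts = int(params.get("restarts", cfg.get("restarts", DEFAULTS["restarts"])))
    fg = params.get("foreground")
    stage_seed = split_seed(seed, "turnover")
    rows = []
    if params.get("per_family", True):
        for i, fam in enumerate(counts.family_ids):
            row = counts.counts[i]
            if row.sum() == 0:
                continue
            fc = FamilyCounts([fam], counts.species, row.reshape(1, -1))
            fits = [fit_turnover(tree, fc, "global", n_restarts=restarts, seed=stage_seed + i)]
            if fg:
                fits.append(
                    fit_turnover(tree, fc, "branch", foreground=fg,
                                 n_restarts=restarts, seed=stage_seed + i)
                )
            sel = compare_models(fits) if len(fits) > 1 else None
            best = sel.best if sel else fits[0]
            call, lost = ("stable", False)
            if sel and sel.significant and best.model == "branch":
                call, lost = classify_family(
                    best, tree, dict(zip(counts.species, row))
                )
            rows.append(
                {
                    "family_id": fam,
                    "best_model": best.model,
                    "lnL": best.loglik,
                    "AIC": best.aic,
                    "evidence_ratio": sel.evidence_ratio if sel else float("nan"),
                    "classification": call,
                    "lost_all": lost,
                    "rates": json.dumps({c: list(v) for c, v in best.rates.rates.items()}),
                }
            )
    else:
        fit = fit_turnover(tree, counts, params.get("model", "global"),
                           foreground=fg, n_restarts=restarts, seed=stage_seed)
        rows.append(
            {
                "family_id": "(joint)",
                "best_model": fit.model,
                "lnL": fit.loglik,
                "AIC": fit.aic,
                "evidence_ratio": float("nan"),
                "classification": "",
                "lost_all": False,
                "rates": json.dumps({c: list(v) for c, v in fit.rates.rates.items()}),
            }
        )
    pd.DataFrame(rows).to_csv(out / "turnover.tsv", sep="\t", index=False)
    return len(rows)


def _run_ks(params, cfg, seed, out: Path) -> int:
    seqs = read_codon_fasta(params["pairs"])
    ids = list(seqs)
    if len(ids) % 2 != 0:
        raise ValueError("pairs FASTA must hold an even number of sequences")
    method = params.get("method", "gy")
    restarts = int(params.get("restarts", cfg.get("restarts", DEFAULTS["restarts"])))
    stage_seed = split_seed(seed, "ks")
    rows = []
    for k in range(0, len(ids), 2):
        pair = CodonPair(seqs[ids[k]], seqs[ids[k + 1]])
        est = (
            gy94_fit(pair, n_restarts=restarts, seed=stage_seed + k)
            if method == "gy"
            else ng86_ks(pair)
        )
        rows.append(
            {
                "id1": ids[k],
                "id2": ids[k + 1],
                "method": est.method,
                "t": est.t,
                "kappa": est.kappa,
                "omega": est.omega,
                "dS": est.dS,
                "dN": est.dN,
                "n_codons": est.n_codons,
                "flagged": est.saturated or est.undefined,
            }
        )
    pd.DataFrame(rows).to_csv(out / "ks.tsv", sep="\t", index=False)
    return len(rows)


def _run_peaks(params, cfg, seed, out: Path) -> int:
    df = pd.read_csv(params["ks"], sep="\t")
    col = "dS" if "dS" in df.columns else df.columns[0]
    x = df[col].dropna().to_numpy(dtype=float)
    wcol = params.get("weights_column")
    w = df.loc[df[col].notna(), wcol].to_numpy(dtype=float) if wcol else None
    lo, hi = cfg.get("ks_window", DEFAULTS["ks_window"])
    filtered = filter_ks(x, w, lo, hi)
    x, w = (filtered if w is not None else (filtered, None))
    stage_seed = split_seed(seed, "peaks")
    kmax = int(params.get("kmax", cfg.get("kmax", DEFAULTS["kmax"])))
    if params.get("select", "bic") == "boot":
        B = int(params.get("B", cfg.get("B", DEFAULTS["B"])))
        alpha = float(params.get("alpha", cfg.get("alpha", DEFAULTS["alpha"])))
        k = select_k_bootstrap(x, kmax=kmax, B=B, alpha=alpha, seed=stage_seed)
        from .gmm_peaks import em_fit

        fit = em_fit(x, w, k=k, seed=stage_seed)
    else:
        fit = select_k_bic(x, w, kmax=kmax, seed=stage_seed)
    peaks = peak_confidence_intervals(
        fit, x, w, B=int(params.get("ci_B", 500)), seed=stage_seed + 1
    )
    pd.DataFrame(
        {
            "mean": peaks.means,
            "ci_lo": peaks.ci_lo,
            "ci_hi": peaks.ci_hi,
            "proportion": peaks.proportions,
        }
    ).to_csv(out / "peaks.tsv", sep="\t", index=False)
    return fit.k


def _run_nupt(params, cfg, seed, out: Path) -> int:
    hits = read_blast_tab(params["hits"])
    scaf_lens = None
    if params.get("scaffold_lens"):
        scaf_lens = {
            r[0]: int(r[1])
            for r in (l.split("\t") for l in Path(params["scaffold_lens"]).read_text().splitlines() if l)
        }
    summ = summarize_nupt(hits, int(params["genome_bp"]), merge=bool(params.get("merge", False)),
                          scaffold_lengths=scaf_lens)
    pd.DataFrame([{
        "n_hits": summ.n_hits,
        "n_scaffolds_hit": summ.n_scaffolds_hit,
        "total_aligned_bp": summ.total_aligned_bp,
        "genome_bp": summ.genome_bp,
        "fraction_pct": 100.0 * summ.fraction,
        "min_len": summ.min_len,
        "max_len": summ.max_len,
        "mean_len": summ.mean_len,
        "median_len": summ.median_len,
        "n_scaffolds_over_2kb": summ.n_scaffolds_over_2kb,
    }]).to_csv(out / "nupt_summary.tsv", sep="\t", index=False)
    if hits:
        write_circos_links(color_links(hits), out / "nupt_links.txt")
    return summ.n_hits


def _run_enrich(params, cfg, seed, out: Path) -> int:
    ann = read_annotations(params["annotations"])
    subset = [l.strip() for l in Path(params["subset"]).read_text().splitlines() if l.strip()]
    universe = None
    if params.get("universe"):
        universe = [l.strip() for l in Path(params["universe"]).read_text().splitlines() if l.strip()]
    alpha = float(params.get("alpha", cfg.get("fisher_alpha", DEFAULTS["fisher_alpha"])))
    results = enrich_terms(subset, ann, universe, alpha=alpha)
    pd.DataFrame([r.__dict__ for r in results]).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return len(results)


_STAGE_FNS = {
    "turnover": _run_turnover,
    "ks": _run_ks,
    "peaks": _run_peaks,
    "nupt": _run_nupt,
    "enrich": _run_enrich,
}
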