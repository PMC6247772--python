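"""End-to-end landmark and outline pipelines.

Each pipeline runs: size variables (centroid size or perimeter) with
per-species summaries and pairwise permutation tests; shape variables
(partial-warp scores or normalized elliptic Fourier coefficients);
discriminant analysis with a factor map; pairwise Mahalanobis distances
with permutation tests (Bonferroni over all pairs); validated leave-one-out
reclassification; a bootstrap single-linkage classification tree plus a
UPGMA comparator; and an allometry summary.  All randomness derives from
the single config seed, and every report records the config it was run
with, so runs are reproducible byte for byte.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discrimination, landmarks, outlines, stats, trees
from .io import MorphoDataset, write_report_tables

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PipelineReport",
    "run_landmark_pipeline",
    "run_outline_pipeline",
    "compare_methods",
    "write_bundle",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    mode: str = "both"            # landmark | outline | both
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 20180611
    var_fraction: float = 0.95
    harmonics: int = 12
    n_boot: int = 100
    resample_points: int = 100
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("landmark", "outline", "both"):
            raise ValueError(f"invalid mode {self.mode!r}")
        for name in ("n_perm", "harmonics", "n_boot", "resample_points"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.var_fraction <= 1:
            raise ValueError("var_fraction must be in (0, 1]")


@dataclass
class PipelineReport:
    mode: str
    config: PipelineConfig
    specimen_ids: list
    species: list                      # per-specimen labels
    group_labels: list
    sizes: np.ndarray                  # mm
    size_summary: pd.DataFrame
    size_tests: dict                   # frozenset pair -> PermutationResult
    shape_vars: np.ndarray
    model: discrimination.DiscriminantModel
    mahalanobis: pd.DataFrame
    shape_tests: dict
    factor_xy: np.ndarray
    hulls: dict
    reclassification: discrimination.ReclassificationReport
    tree: trees.ClassificationTree
    upgma_tree: trees.ClassificationTree
    allometry: stats.AllometryResult
    extras: dict = field(default_factory=dict)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def _pair_seed(base: int, family: int, index: int) -> int:
    return int(np.random.SeedSequence([base, family, index]).generate_state(1)[0] % 2**31)


def _pairwise_tests(test_fn, labels_sorted, n_perm, base_seed, family, **kw):
    results = {}
    for idx, (a, b) in enumerate(itertools.combinations(labels_sorted, 2)):
        results[frozenset((a, b))] = test_fn(
            group_a=a, group_b=b, n_perm=n_perm,
            seed=_pair_seed(base_seed, family, idx), **kw,
        )
    m = len(results)
    for r in results.values():
        r.adjust(m)
    return results


def _discrimination_stages(
    shape_vars, labels, sizes, specimen_ids, config, mode, size_summary,
    size_tests, extras,
):
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    with _stage("discriminant analysis"):
        model = discrimination.fit_da(shape_vars, labels, config.var_fraction)
        xy, hulls = discrimination.factor_map(model)
        maha = pd.DataFrame(model.mahalanobis, index=groups, columns=groups)
    with _stage("shape permutation tests"):
        shape_tests = _pairwise_tests(
            lambda **kw: stats.perm_test_shape(
                shape_vars, labels, var_fraction=config.var_fraction, **kw
            ),
            groups, config.n_perm, config.seed, family=2,
        )
    with _stage("validated reclassification"):
        reclass = discrimination.loo_reclassify(
            shape_vars, labels, config.var_fraction
        )
    with _stage("classification trees"):
        tree = trees.bootstrap_tree(
            shape_vars, labels, config.n_boot,
            seed=_pair_seed(config.seed, 3, 0),
            var_fraction=config.var_fraction,
        )
        upgma_tree = trees.upgma(model.mahalanobis, groups)
    with _stage("allometry"):
        allo = stats.allometry(model.factor_scores, sizes)
    return PipelineReport(
        mode=mode,
        config=config,
        specimen_ids=list(specimen_ids),
        species=labels.tolist(),
        group_labels=groups,
        sizes=np.asarray(sizes, float),
        size_summary=size_summary,
        size_tests=size_tests,
        shape_vars=np.asarray(shape_vars, float),
        model=model,
        mahalanobis=maha,
        shape_tests=shape_tests,
        factor_xy=xy,
        hulls=hulls,
        reclassification=reclass,
        tree=tree,
        upgma_tree=upgma_tree,
        allometry=allo,
        extras=extras,
    )


def _size_stages(sizes, labels, config):
    groups = sorted(set(labels))
    with _stage("size summary"):
        summary = stats.quantile_summary(sizes, labels)
    with _stage("size permutation tests"):
        size_tests = _pairwise_tests(
            lambda **kw: stats.perm_test_size(sizes, labels, **kw),
            groups, config.n_perm, config.seed, family=1,
        )
        letters = stats.significance_letters(
            groups,
            {pair: r.p_adj for pair, r in size_tests.items()},
            config.alpha,
        )
        summary["letter"] = [letters[g] for g in summary.index]
    return summary, size_tests


def run_landmark_pipeline(
    dataset: MorphoDataset, config: PipelineConfig | None = None
) -> PipelineReport:
    """Landmark pipeline: CS -> GPA -> partial/relative warps -> DA and the
    shared discrimination/statistics/tree stages."""
    config = config or PipelineConfig()
    if len(dataset.species_table) < 2:
        raise PipelineError("stage 'input': need at least 2 species")
    records = dataset.records
    if any(r.scale_defaulted for r in records):
        raise PipelineError(
            "stage 'input': dataset contains defaulted scale factors; "
            "size analyses need real mm-per-pixel scales"
        )
    labels = [r.species for r in records]
    ids = [r.specimen_id for r in records]
    with _stage("centroid size"):
        sizes = np.array([landmarks.centroid_size(r) for r in records])
    size_summary, size_tests = _size_stages(sizes, labels, config)
    with _stage("Procrustes superimposition"):
        fit = landmarks.gpa(dataset)
        landmarks.partial_warps(fit)
        rw_scores, rw_explained = landmarks.relative_warps(fit)
    extras = {
        "gpa_iterations": fit.iterations,
        "rw_explained": rw_explained,
        "mean_shape": fit.mean_shape,
    }
    return _discrimination_stages(
        fit.pw_scores, labels, sizes, ids, config, "landmark",
        size_summary, size_tests, extras,
    )


def run_outline_pipeline(
    dataset: MorphoDataset, config: PipelineConfig | None = None
) -> PipelineReport:
    """Outline pipeline: perimeter -> EFA -> NEF -> DA and the shared
    discrimination/statistics/tree stages."""
    config = config or PipelineConfig()
    if len(dataset.species_table) < 2:
        raise PipelineError("stage 'input': need at least 2 species")
    records = dataset.records
    if any(r.scale_defaulted for r in records):
        raise PipelineError(
            "stage 'input': dataset contains defaulted scale factors; "
            "size analyses need real mm-per-pixel scales"
        )
    labels = [r.species for r in records]
    ids = [r.specimen_id for r in records]
    with _stage("perimeter"):
        sizes = np.array([outlines.perimeter_length(r) for r in records])
    size_summary, size_tests = _size_stages(sizes, labels, config)
    with _stage("elliptic Fourier analysis"):
        nef = []
        for r in records:
            rs = outlines.resample_contour(r, config.resample_points)
            dec = outlines.normalize_efa(outlines.efa(rs, config.harmonics))
            nef.append(dec.nef)
        nef = np.asarray(nef)
    extras = {"harmonics": config.harmonics}
    return _discrimination_stages(
        nef, labels, sizes, ids, config, "outline",
        size_summary, size_tests, extras,
    )


def compare_methods(report_lm: PipelineReport, report_out: PipelineReport) -> dict:
    """Side-by-side comparison of the two pipelines on the same specimens.

    Returns per-species reclassification percentages, the Spearman rank
    correlation of the pairwise Mahalanobis distances, and the leaf
    bipartitions shared by the two single-linkage trees.
    """
    if report_lm.specimen_ids != report_out.specimen_ids:
        raise PipelineError(
            "stage 'compare': the two reports cover different specimen sets"
        )
    groups = report_lm.group_labels
    rows = []
    for g in groups:
        c_lm, t_lm, p_lm = report_lm.reclassification.per_species[g]
        c_out, t_out, p_out = report_out.reclassification.per_species[g]
        rows.append(
            {
                "landmark": f"{round(p_lm)}% ({c_lm}/{t_lm})",
                "outline": f"{round(p_out)}% ({c_out}/{t_out})",
            }
        )
    table = pd.DataFrame(rows, index=groups)

    iu = np.triu_indices(len(groups), k=1)
    d_lm = report_lm.mahalanobis.to_numpy()[iu]
    d_out = report_out.mahalanobis.to_numpy()[iu]
    from scipy.stats import spearmanr

    rho = float(spearmanr(d_lm, d_out).statistic) if d_lm.size > 1 else 1.0

    bip_lm = report_lm.tree.bipartitions
    bip_out = report_out.tree.bipartitions
    shared = bip_lm & bip_out
    return {
        "reclassification": table,
        "distance_rank_correlation": rho,
        "shared_bipartitions": shared,
        "n_shared_bipartitions": len(shared),
        "n_bipartitions": (len(bip_lm), len(bip_out)),
    }


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_bundle(report: PipelineReport, out_dir) -> list:
    """Write a report bundle as plain CSV / Newick / text files.

    Output is deterministic: identical reports produce byte-identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = report.group_labels
    flags = pd.DataFrame(
        [
            [
                i != j
                and report.shape_tests[frozenset((groups[i], groups[j]))].p_adj
                < report.config.alpha
                for j in range(len(groups))
            ]
            for i in range(len(groups))
        ],
        index=groups,
        columns=groups,
    )
    written = write_report_tables(
        {
            "size_summary": report.size_summary,
            "mahalanobis": report.mahalanobis,
            "mahalanobis_flags": flags,
            "reclassification": report.reclassification.to_frame(),
        },
        out_dir,
    )

    tests_rows = []
    for family, results in (("size", report.size_tests), ("shape", report.shape_tests)):
        for pair in sorted(results, key=lambda p: tuple(sorted(p))):
            r = results[pair]
            a, b = sorted(pair)
            tests_rows.append(
                {
                    "family": family,
                    "group_a": a,
                    "group_b": b,
                    "observed": _fmt(r.observed),
                    "p_raw": _fmt(r.p_raw),
                    "p_adj": _fmt(r.p_adj),
                    "n_perm": r.n_perm,
                }
            )
    p = out_dir / "permutation_tests.csv"
    pd.DataFrame(tests_rows).to_csv(p, index=False)
    written.append(p)

    p = out_dir / "factor_scores.csv"
    pd.DataFrame(
        {
            "specimen_id": report.specimen_ids,
            "species": report.species,
            "axis1": [_fmt(v) for v in report.factor_xy[:, 0]],
            "axis2": [_fmt(v) for v in report.factor_xy[:, 1]],
            "size_mm": [_fmt(v) for v in report.sizes],
        }
    ).to_csv(p, index=False)
    written.append(p)

    p = out_dir / "tree_single_linkage.nwk"
    p.write_text(trees.to_newick(report.tree) + "\n")
    written.append(p)
    p = out_dir / "tree_upgma.nwk"
    p.write_text(trees.to_newick(report.upgma_tree) + "\n")
    written.append(p)

    merge_rows = [
        {
            "cluster_a": "|".join(a),
            "cluster_b": "|".join(b),
            "height": _fmt(h),
            "support": _fmt(report.tree.support.get(frozenset(a + b), float("nan"))),
        }
        for a, b, h in report.tree.merges
    ]
    p = out_dir / "tree_merges.csv"
    pd.DataFrame(merge_rows).to_csv(p, index=False)
    written.append(p)

    summary = {
        "mode": report.mode,
        "config": asdict(report.config),
        "n_specimens": len(report.specimen_ids),
        "n_species": len(groups),
        "overall_reclassification_percent": round(
            report.reclassification.overall_percent, 4
        ),
        "allometry_r2_percent": round(report.allometry.r2_percent, 4),
        "n_significant_shape_pairs": int(
            sum(
                r.p_adj < report.config.alpha
                for r in report.shape_tests.values()
            )
        ),
        "n_significant_size_pairs": int(
            sum(r.p_adj < report.config.alpha for r in report.size_tests.values())
        ),
        "n_pairs": len(report.shape_tests),
    }
    p = out_dir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written
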