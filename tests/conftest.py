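import numpy as np
import pandas as pd
import pytest

import adrenomir as am

from adrenomir.workflows import BEST_PANEL_MARKERS, TOP5_IMPORTANCE  # noqa: F401


@pytest.fixture(scope="session")
def study_spec():
    """Study-like synthetic conditions: strong effects on the best-panel
    markers, weaker background effects elsewhere."""
    return am.spec_with_marker_effects(BEST_PANEL_MARKERS, 2.0, 0.5)


@pytest.fixture(scope="session")
def null_spec():
    """No group effect anywhere: every marker identically distributed."""
    return am.default_spec(effect_log2=0.0, aca_vs_nac_log2=0.0)


@pytest.fixture(scope="session")
def discovery_matrix(study_spec):
    table, _ = am.generate_cohort(study_spec, "discovery", seed=1)
    return am.DeltaCtNormalizer().fit_transform(table)


@pytest.fixture(scope="session")
def validation_matrix(study_spec):
    table, truth = am.generate_cohort(study_spec, "validation", seed=1)
    return am.DeltaCtNormalizer().fit_transform(table), truth


def run_all_stages(tmp_path, seed=1):
    """Drive every CLI stage end to end in ``tmp_path``.

    Returns {stage_name: output_bytes} for the files each stage wrote.
    """
    from click.testing import CliRunner

    from adrenomir.cli import main as cli_main

    runner = CliRunner()
    paths = {name: tmp_path / name for name in (
        "ct_d.csv", "truth_d.csv", "ct_v.csv", "truth_v.csv", "expr_d.csv",
        "expr_v.csv", "importance.csv", "expr_small.csv", "models.csv",
        "votes.csv", "report.csv")}

    def run(args):
        result = runner.invoke(cli_main, args, catch_exceptions=False)
        assert result.exit_code == 0, result.output
        return result

    run(["simulate", "--cohort", "discovery", "--seed", str(seed),
         "--out", str(paths["ct_d.csv"]), "--truth", str(paths["truth_d.csv"])])
    run(["simulate", "--cohort", "validation", "--seed", str(seed),
         "--out", str(paths["ct_v.csv"]), "--truth", str(paths["truth_v.csv"])])
    run(["normalize", "--in", str(paths["ct_d.csv"]),
         "--out", str(paths["expr_d.csv"])])
    run(["normalize", "--in", str(paths["ct_v.csv"]),
         "--out", str(paths["expr_v.csv"])])
    run(["rank", "--in", str(paths["expr_d.csv"]), "--trees", "50",
         "--seed", str(seed), "--out", str(paths["importance.csv"])])
    # small marker subset keeps the exhaustive search quick
    expr = pd.read_csv(paths["expr_d.csv"], index_col="sample_id")
    keep = ["group", "hsa-miR-195", "hsa-miR-210", "hsa-miR-483-5p",
            "hsa-miR-503"]
    expr[keep].to_csv(paths["expr_small.csv"])
    run(["search", "--in", str(paths["expr_small.csv"]), "--mode", "two_class",
         "--reps", "20", "--sizes", "2:2", "--seed", str(seed),
         "--out", str(paths["models.csv"])])
    run(["classify", "--known", str(paths["expr_d.csv"]),
         "--unknown", str(paths["expr_v.csv"]),
         "--model", "hsa-miR-195 + hsa-miR-210 + hsa-miR-503",
         "--iterations", "50", "--seed", str(seed),
         "--out", str(paths["votes.csv"])])
    run(["evaluate", "--votes", str(paths["votes.csv"]),
         "--truth", str(paths["truth_v.csv"]),
         "--out", str(paths["report.csv"])])
    return {name: path.read_bytes() for name, path in paths.items()
            if path.exists()}


def toy_ct_frame(n_samples=3, assays=("hsa-miR-195", "RNU48", "cel-miR-39"),
                 n_reps=3, ct=30.0, group="ACA"):
    """Small fully observed long-form Ct table."""
    rows = []
    for i in range(n_samples):
        for a in assays:
            for r in range(1, n_reps + 1):
                rows.append((f"S{i + 1}", group, a, r, ct))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "assay", "replicate", "ct"]
    )


def make_matrix(values: np.ndarray, groups, assays=None, prefix="S"):
    """ExpressionMatrix from a dense array and a group list."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    assays = list(assays) if assays is not None else [f"m{j}" for j in range(p)]
    index = [f"{prefix}{i + 1:02d}" for i in range(n)]
    return am.ExpressionMatrix(
        values=pd.DataFrame(values, index=index, columns=assays),
        groups=pd.Series(list(groups), index=index),
    )
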