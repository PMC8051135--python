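"""Enrichment statistics over the planted dataset.

Runs the expression-matched permutation test (10,000 iterations) for
stretch-enhancer proximity to the planted 25-gene signature set, the
bound-vs-unbound expression comparison, nearest-gene fold-changes by
stretch-enhancer specificity, the top-5% differential-expression
selection, a channel-gene-style one-way ANOVA, and example co-staining
proportions. Writes results/enrichment.json and
results/expression_stats.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from chromenh.enhancers import shared_enhancers
from chromenh.simulate import SimulationConfig, simulate_dataset
from chromenh.stats import (
    bound_vs_unbound_expression_test,
    costain_proportions,
    group_expression_anova,
    nearest_gene_log2fc,
    permutation_enrichment_test,
    select_top_percent_de,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    ds = simulate_dataset(cfg, with_sequence=False, with_tracks=False)
    cond_a, cond_b = cfg.conditions

    res = permutation_enrichment_test(
        ds.gene_truth["signature_ids"],
        ds.genes,
        ds.expression,
        ds.enhancers[cond_b].stretch(),
        cond_b,
        n_permutations=10_000,
        seed=SEED,
    )
    print(
        f"Signature enrichment: observed {res.observed} distinct stretch "
        f"enhancers within 50 kb; null mean {res.null_counts.mean():.1f}, "
        f"max {res.null_counts.max()}; empirical p = {res.empirical_p:.4g} "
        f"(add-one {res.add_one_p:.4g})"
    )

    u, p_mw = bound_vs_unbound_expression_test(
        ds.expression, ds.gene_truth["bound_ids"], cond_b
    )

    # nearest-gene fold change by stretch-enhancer specificity
    rep = shared_enhancers(
        type(ds.enhancers[cond_a])(cond_a, ds.enhancers[cond_a].stretch()),
        type(ds.enhancers[cond_b])(cond_b, ds.enhancers[cond_b].stretch()),
        0.25,
    )
    enh = list(ds.enhancers[cond_a].stretch()) + list(ds.enhancers[cond_b].stretch())
    labels = [
        "shared" if lab == "shared" else "a_specific" for lab in rep.labels_a
    ] + ["shared" if lab == "shared" else "b_specific" for lab in rep.labels_b]
    lfc = nearest_gene_log2fc(enh, labels, ds.genes, ds.expression, cond_b, cond_a)
    medians = {k: float(np.median(v)) for k, v in lfc.items()}

    top_up = select_top_percent_de(ds.expression, cond_b, cond_a, percent=5)
    top_down = select_top_percent_de(ds.expression, cond_a, cond_b, percent=5)

    # channel-gene-style grouped ANOVA on three random gene families
    rng = np.random.default_rng(SEED)
    fam = rng.choice(ds.expression.gene_ids, size=15, replace=False)
    groups = [
        ds.expression.values(cond_b, fam[:5]),
        ds.expression.values(cond_b, fam[5:10]),
        ds.expression.values(cond_b, fam[10:]),
    ]
    f_stat, p_anova = group_expression_anova(groups)

    props = [costain_proportions(*pair) for pair in [(5, 11), (8, 26), (8, 270)]]

    stats = pd.DataFrame(
        [
            {"metric": "mannwhitney_U_bound_vs_unbound", "value": u},
            {"metric": "mannwhitney_p", "value": p_mw},
            {"metric": "median_log2fc_a_specific", "value": round(medians.get("a_specific", np.nan), 3)},
            {"metric": "median_log2fc_b_specific", "value": round(medians.get("b_specific", np.nan), 3)},
            {"metric": "median_log2fc_shared", "value": round(medians.get("shared", np.nan), 3)},
            {"metric": "n_top5pct_up", "value": len(top_up)},
            {"metric": "n_top5pct_down", "value": len(top_down)},
            {"metric": "anova_F_random_families", "value": round(f_stat, 3)},
            {"metric": "anova_p_random_families", "value": round(p_anova, 3)},
        ]
        + [
            {"metric": f"costain_{p.numerator}_{p.denominator}_percent", "value": p.percent}
            for p in props
        ]
    )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    payload = {
        "observed": res.observed,
        "empirical_p": res.empirical_p,
        "add_one_p": res.add_one_p,
        "n_permutations": res.n_permutations,
        "seed": res.seed,
        "parameters": res.parameters,
        "null_histogram": {
            str(int(r["count"])): int(r["n_permutations"])
            for _, r in res.null_histogram().iterrows()
        },
    }
    (results / "enrichment.json").write_text(json.dumps(payload, indent=2) + "\n")
    stats.to_csv(results / "expression_stats.tsv", sep="\t", index=False)

    print(stats.to_string(index=False))
    print(
        "\nFinding: the planted signature set sits near far more stretch "
        "enhancers than expression-matched random sets, and promoter-bound "
        "genes are significantly more highly expressed. Nearest-gene "
        "fold-changes are reported per specificity group; the generator "
        "plants no expression effect at stretch enhancers, so those medians "
        "stay near zero."
    )


if __name__ == "__main__":
    main()
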