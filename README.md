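# tdaseq

Topological stratification of bulk RNA-seq cohorts. `tdaseq` takes an
expression matrix (FPKM, genes × subjects) with healthy/tumor labels and

1. **standardizes** each subject's log₂(FPKM) profile under a fitted
   two-component Gaussian mixture (scores T₀–T₃),
2. **summarizes** the cohort as a Mapper graph — an overlapping-bin cover
   of a mean-correlation filter with per-bin agglomerative clustering —
   whose strand-like shape separates tumor subpopulations,
3. **labels** each subject with a position index PI ∈ {+1, 0, −1} (one
   strand end, middle, other end) and exports the PI subgroups for
   differential-expression tooling,
4. **scores** each subject with a heat-kernel-signature-based graphical
   subject score (GSS) on the doubly-weighted Mapper graph, and
5. **quantifies** robustness to the Mapper parameters (b, p, ε) with
   vary-one-fix-two empirical 95% confidence intervals of the GSS.

It is aimed at computational biologists exploring tumor/healthy bulk
RNA-seq cohorts who want a graph-shaped, parameter-auditable alternative
to t-SNE-style embeddings. A seeded synthetic-cohort generator makes the
whole pipeline testable without external data.

## The model in brief

Per subject, log₂ expression follows a mixture
`f(x) = Σⱼ cⱼ N(x; μⱼ, σⱼ)` with membership weights
`ωⱼ(x) = cⱼN(x; μⱼ, σⱼ) / Σₖ cₖN(x; μₖ, σₖ)`. The default score T₀ is
the z-score under the hard-assigned (argmax ωⱼ) component. Mapper uses a
filter f(subject) = mean Pearson correlation against the rest of the
cohort, b equal-length intervals with p% overlap covering [min f, max f],
and single-linkage clustering cut at scale ε inside each interval; nodes
are clusters, edges join clusters sharing subjects, weighted by the
shared count.

A labeled Mapper graph becomes a doubly-weighted graph G = (V, M, W):
`W_ij` = shared-subject count, `m_i` = smoothed tumor fraction of node i.
With the weighted Laplacian `L = M^(−1/2)(D − W)M^(−1/2)` and eigenpairs
{λₖ, φₖ}, the heat kernel signature of node i at diffusion time t is

```
ν_i(t) = Σₖ exp(−t λₖ) φₖ(i)²
```

and a subject's GSS is the sum of ν_i(t) over the nodes containing it
(default t = 1/λ₂ per connected component). See `docs/methods.md` for
assumptions, defaults, numerical conventions, and limitations.

## Worked example

```python
import numpy as np
from tdaseq import gmm, mapper, pi, spectral, synthetic

cfg = synthetic.CohortConfig(n_healthy=30, n_tumor_A=10, n_tumor_B=60,
                             n_genes=300, n_effect_genes=60, seed=7)
cohort = synthetic.generate_cohort(cfg)
scores, fits, gof = gmm.compute_score_matrix(
    cohort.fpkm, kind="T0", seed=0, pseudo_count=0.0
)
print(f"KS non-reject rate: {1 - gof['reject'].mean():.2f}")
fit = fits[cohort.subject_ids[0]]
print(f"first subject mixture: means={np.round(fit.means, 2)}, "
      f"sds={np.round(fit.sds, 2)}, weights={np.round(fit.weights, 2)}")

X = scores.to_numpy()
eps = synthetic.suggest_epsilon(X)
graph = mapper.build_mapper(
    X, mapper.MapperParams(b=12, p=50, epsilon=eps), cohort.subject_ids
)
order, strandlike = pi.linearize_nodes(graph)
print(f"mapper: {graph.n_nodes} nodes, {len(graph.edges)} edges "
      f"(epsilon={eps:.1f}, strandlike={strandlike})")

assignment = pi.assign_position_index(graph, 0.25)
for val in (+1, -1):
    ids = assignment.values.index[assignment.values == val]
    tumor = np.mean([cohort.labels[s] == "tumor" for s in ids])
    print(f"PI={val:+d}: {len(ids)} subjects, {100*tumor:.0f}% tumor")

gss = spectral.compute_gss(graph, cohort.labels, t="auto")
healthy = cohort.labels == "healthy"
print(f"GSS (t={gss.t:.2f}): healthy mean "
      f"{gss.scores[healthy].mean():.3f}, tumor mean "
      f"{gss.scores[~healthy].mean():.3f}")
```

prints

```
KS non-reject rate: 1.00
first subject mixture: means=[3.5  9.04], sds=[2.7  1.73], weights=[0.51 0.49]
mapper: 12 nodes, 11 edges (epsilon=23.1, strandlike=True)
PI=+1: 13 subjects, 69% tumor
PI=-1: 49 subjects, 92% tumor
GSS (t=3.02): healthy mean 0.155, tumor mean 0.268
```

Reading this: every subject's log₂ expression is consistent with its
fitted two-mode mixture (KS at α = 0.01 never rejects); the first
subject's fitted modes sit near the generating low/high expression
modes; the Mapper graph is a single 12-node strand; both strand ends are
tumor-enriched (the minority arm shares its end with nearby healthy
subjects in this small cohort, hence 69%); and tumor subjects, sitting
in the small end nodes, retain more heat than the densely connected
healthy middle, hence higher GSS.

## Command line

Every stage is also a `tdaseq` subcommand operating on files:

```bash
tdaseq simulate --seed 42 -o cohort/
tdaseq scores --matrix cohort/fpkm.tsv --kind T0 --pseudo-count 0 -o scores.tsv
tdaseq mapper --scores scores.tsv -b 80 -p 50 -e 600 --filter mean_corr -o graph.graphml
tdaseq pi --scores scores.tsv --fraction 0.25 -o pi.tsv
tdaseq gss --scores scores.tsv --labels cohort/labels.tsv --t auto -o gss.tsv
tdaseq sweep --scores scores.tsv --labels cohort/labels.tsv -o ensemble.tsv
tdaseq ci --ensemble ensemble.tsv --vary epsilon --fixed-b 80 --fixed-p 50 -o ci.tsv
tdaseq run --config pipeline.yaml   # end-to-end, YAML-configured
```

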