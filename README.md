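# icga — independent-component graph analysis of resting-state fMRI

`icga` turns a single-subject ICA decomposition of resting-state BOLD fMRI
into one weighted graph per intrinsic connectivity network (default mode,
auditory, visual, ...), so that within-network organization can be studied
with ordinary graph theory instead of voxel-wise map statistics. It is aimed
at researchers who already have per-subject ICA output (any backend) and an
anatomical parcellation, and want network-resolved connectomes plus the
standard metric battery and group statistics on top of them.

## The method

Let `X` (N×P) hold the time-courses of the N neuronal independent
components and `Y` (R×P) the BOLD signal averaged over each of R
parcellated regions. Ordinary least squares solves `Y = Xβ` (an intercept
column is included), and each coefficient is turned into a t-value

    t_ij = c_i'β_j / sqrt( σ_j² · c_i'(A'A)⁻¹c_i ),   DOF = P − N − 1,

so every region carries one t-value per component. For one component, the
edge weight between regions a and b is

    W(a,b)    = |t_a| + |t_b| − |t_a − t_b|      (correlation network)
    W_AC(a,b) = |t_a| + |t_b| − |t_a + t_b|      (anti-correlation network)

`W` equals `2·min(|t_a|,|t_b|)` when the signs agree and 0 otherwise;
`W_AC` is the opposite-sign complement. Edges with `W < 2·t_threshold`,
where `t_threshold = t⁻¹(1−p, DOF)` at p = .001, are discarded — exactly
the requirement that both node t-values be individually significant. Group
graphs keep edges present in ≥ 25% of subjects. A "classical" whole-brain
graph is built from the artifact-cleaned signal (the sum of the neuronal
components weighted by their spatial maps), region-averaged and correlated
pairwise. On every graph's connected constellation the package computes
edges E, average degree k = 2E/n, triangles, clustering C, characteristic
path length L, and small-worldness σ = (C/C_rand)/(L/L_rand) against
Erdős–Rényi G(n,E) nulls, and compares networks with one-way ANOVA plus
Tukey's HSD.

## Worked example

Simulate a small cohort with known ground truth, run one subject, and read
the numbers off:

```bash
icga simulate --out fixtures --config sim.yaml     # or use the library:
```

```python
from icga import (SyntheticConfig, simulate_subject, fit_glm,
                  compute_t_threshold, build_subject_graph,
                  compute_metrics_record)

s = simulate_subject(SyntheticConfig(seed=7), 0)   # 3 components, 60 regions
table = fit_glm(s["series"], s["decomposition"])
thr = compute_t_threshold(table.dof, 0.001)
print(table.dof, round(thr, 3))                    # -> 146 3.147

g = build_subject_graph(table, 1, "correlation", thr)
rec = compute_metrics_record(g, n_random=10, seed=1)
print(g.n_edges, rec.n_connected_nodes, round(rec.avg_degree, 1))
# -> 380 40 19.0
```

Component 1 loads positively on one 20-region block and negatively on
another, so its correlation graph is the two 20-cliques (380 edges over 40
connected nodes, average degree 19); its anti-correlation graph is the
20×20 bipartite graph between the blocks. The same workflow from the shell:

```bash
icga run --region-timecourses sub/region_timecourses.tsv \
         --ic-timecourses sub/ic_timecourses.tsv --out out/sub-01
icga group --subjects out/sub-01 --subjects out/sub-02 --out out/group
```

which writes per-network edge lists (`<net>_<flavor>.tsv` / `.graphml`),
the t-value table, per-subject metrics JSON, group graphs with per-edge
subject counts, a pooled metrics table and the ANOVA/Tukey report.

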