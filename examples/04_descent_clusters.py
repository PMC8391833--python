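"""Y-STR descent-cluster screening and ASD TMRCA dating.

Builds a pooled multi-country Y-STR database with one implanted male
lineage expansion (18 descendants, founder in Peru, recent expansion in
Ecuador), then runs the full screen: rank haplotypes by frequency, keep
frequent cores, grow clusters within two mutational steps, profile
geography and date each cluster by the average squared distance from its
core under the stepwise mutation model (E[ASD] = mu * T per locus).
"""

from unipargen.clusters import TmrcaConfig, cluster_table, find_descent_clusters
from unipargen.simulate import DescentScenarioConfig, sim_descent_scenario

cfg = DescentScenarioConfig(seed=11)
pooled, meta, truth = sim_descent_scenario(cfg)
print(f"pooled database: {len(pooled)} chromosomes, "
      f"{len(truth['member_ids'])} implanted descendants "
      f"(source country: {truth['source_country']})")

clusters, unassigned = find_descent_clusters(
    pooled, meta, tmrca_config=TmrcaConfig(mu=cfg.mu_str, seed=1)
)
print(f"\n{len(clusters)} cluster(s); {len(unassigned)} chromosomes unassigned")
print(cluster_table(clusters).to_string(index=False))

top = clusters[0]
got = {h.sample_id for h in top.members}
true_ids = set(truth["member_ids"])
tp = len(got & true_ids)
f1 = 2 * tp / (len(got) + len(true_ids))
print(
    f"\ntop cluster: n={top.n}, membership F1 = {f1:.2f}, "
    f"inferred origin = {','.join(top.inferred_origin)} "
    f"(truth: {truth['source_country']})"
)
print(
    "Frequency peaks in the spread country while allele-size variance peaks\n"
    "at the source - the geography signature of an old lineage that expanded\n"
    "recently elsewhere. The ASD clock dates the *core's* expansion, so with\n"
    "most members from the recent spread it bounds the full TMRCA from below."
)
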