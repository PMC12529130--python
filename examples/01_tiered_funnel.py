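"""Run a three-tier top-10% screening funnel over a synthetic library.

Mirrors the shape of a real docking campaign: a large scored library is
cut to its best 10% at each of three tiers (coarse, standard, precise),
so n molecules become about n/1000 finalists.
"""

from winfunnel.cascade import ScoredItem, TierSpec, run_funnel
from winfunnel.fixtures import gen_scores

N = 50_000
scores = gen_scores(N, seed=11)
items = [ScoredItem(id=f"C{i}", scores={"htvs": s, "sp": s, "xp": s})
         for i, s in enumerate(scores)]

tiers = [TierSpec(name=t, selection=("top_fraction", 0.10))
         for t in ("htvs", "sp", "xp")]
report, survivors = run_funnel(items, tiers)

for row in report.rows:
    print(f"{row['tier']}: {row['n_in']:>6} -> {row['n_out']:>5}"
          f"  ({row['rule']})")
print(f"finalists: {len(survivors)} of {N} "
      "(floor(0.1*n) applied at each tier)")
best = min(survivors, key=lambda i: i.scores["xp"])
print(f"best finalist {best.id} scored {best.scores['xp']:.2f} kcal/mol")
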