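"""Hypergeometric term enrichment on a 10-gene toy universe.

The universe holds 10 annotated genes; term T1 covers 5 of them.  Of 4
candidate genes, 3 carry T1.  The upper-tail probability of drawing at
least 3 term genes in 4 draws is 55/210 ~= 0.2619 — the worked
hypergeometric example, unadjusted and far from significant.
"""

from mircycle.enrichment import AnnotationUniverse, hypergeom_p, run_enrichment

p = hypergeom_p(N=10, n=4, M=5, m=3)
print(f"P(overlap >= 3 | N=10, n=4, M=5) = {p:.6f}  (= 55/210)")

universe = AnnotationUniverse(
    term_genes={
        "T1": {f"g{i}" for i in range(5)},
        "T2": {f"g{i}" for i in range(10)},
    }
)
results = run_enrichment(["g0", "g1", "g2", "g9"], universe, mode="GO")
print(f"{'term':<6}{'N':>4}{'n':>4}{'M':>4}{'m':>4}{'p_raw':>10}{'p_adj':>10}  sig")
for r in results:
    print(
        f"{r.term:<6}{r.N:>4}{r.n:>4}{r.M:>4}{r.m:>4}"
        f"{r.p_raw:>10.4f}{r.p_adjusted:>10.4f}  {r.significant}"
    )
print(
    "\nBonferroni multiplies each raw p by the number of tested terms;\n"
    "neither term reaches the 0.05 cut-off in this toy universe."
)
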