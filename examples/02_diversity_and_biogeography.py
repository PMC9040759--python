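"""Alpha/beta diversity, the latitudinal gradient and distance decay.

Computes per-sample richness and Shannon diversity, then fits the two
classic biogeographic regressions: richness vs absolute latitude (LDG)
and log10 community similarity vs log10 geographic distance (DDR). A more
negative DDR slope means faster spatial turnover. At the default
simulation conditions decay is shallow (deep sequencing keeps richness
saturated and the neutral component adds noise), but the taxon table
consistently decays faster than the trait table.
"""

from ncycomm import SyntheticConfig, bray_curtis, ddr, geo_distance, ldg, make_community, similarity_from
from ncycomm.diversity import alpha_diversity

config = SyntheticConfig(n_stations=10, n_taxa=150, n_traits=30, seed=1)
metadata, taxon, trait, _ = make_community(config)

alpha = alpha_diversity(taxon)
print("per-sample alpha diversity (first 3 rows):")
print(alpha.head(3).to_string())

geo = geo_distance(metadata)
fit = ldg(alpha["richness"], metadata)
print(f"\nLDG: slope {fit.slope:+.3f} richness units per degree |latitude| "
      f"(r2={fit.r2:.2f}, p={fit.p_value:.3g})")

for name, table in (("taxon", taxon), ("trait", trait)):
    f = ddr(similarity_from(bray_curtis(table)), geo, n_perm=199, rng=0)
    print(f"DDR {name}: slope {f.slope:+.4f} (r2={f.r2:.2f}, "
          f"permutation p={f.p_permutation:.3f}, {f.n} pairs)")
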