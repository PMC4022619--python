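# aguadanet

Drought-scenario connectivity analysis of waterhole networks.

In highly seasonal karst landscapes such as the Greater Calakmul Region of
the Yucatán Peninsula, surface water exists only in scattered seasonal
waterholes (*aguadas*). Water-dependent large mammals — Baird's tapir,
white-lipped peccary, jaguar — must move between waterholes, and droughts
dry the smallest waterholes first, eroding the spatial network of reachable
water. `aguadanet` is a toolkit for landscape ecologists to quantify that
erosion: it extracts species-specific spatial graphs from a waterhole layer,
deletes waterholes in increasing order of surface area ("drought
scenarios"), and measures what remains — link density, connected clusters,
the probability-of-connectivity numerator, per-waterhole importance, and
buffer-based suitable habitat.

## The model

- **Nodes** are waterholes (centroid in projected meters, surface area
  *aᵢ* in m²). **Links** join centroids whose Euclidean distance is at most
  a species' maximum movement distance *d*; link density
  *L = links / [n(n−1)/2]*.
- **Drought scenarios** A–K delete all waterholes with area ≤ T for an
  increasing ladder of thresholds T (A is the base network of waterholes
  > 700 m²; B–K use T = 1,000 … 62,500 m²), emulating the observed
  smallest-dry-first pattern.
- **Dispersal kernel**: link probability *p(ℓ) = exp(−kℓ)* with
  *k = −ln(0.05)/d*, so the chance of moving farther than the species'
  maximum distance is 5%.
- **Probability of connectivity (PC) numerator**:
  *Σᵢ Σⱼ aᵢ aⱼ p\*ᵢⱼ* over ordered node pairs (self-pairs included,
  *p\*ᵢᵢ = 1*), where *p\*ᵢⱼ* is the maximum over paths of the product of
  link probabilities — computed as a shortest path under weights −ln p.
- **Node importance**: patch removal. *dPCₖ = 100·(PC − PC₋ₖ)/PC*, the
  percentage of the PC numerator lost when waterhole *k* is deleted;
  aggregated by summation across distance thresholds to rank waterholes.
- **Suitable habitat**: the union of 1 and 2 km buffers grown around each
  waterhole's edge, clipped to the study boundary; overlapping buffers merge
  into connected habitat patches.

Because real waterhole coordinates for such studies are rarely published,
the package ships a synthetic landscape generator (`aguadanet.synthetic`)
that emulates the documented structure: 187 waterholes over ~750 km², a
truncated power-law size distribution on 700–172,500 m², Thomas-process
spatial clustering, and a tunable coupling that places large waterholes
preferentially east of a protected-area strip.

## Worked example

```python
from aguadanet import *
from aguadanet.synthetic import SyntheticConfig, generate_landscape

table, area = generate_landscape(SyntheticConfig(seed=42))
net = build_complete_network(table)          # 17,391 potential links (n = 187)
pruned = prune_by_distance(net, 13_000.0)    # tapir-scale movement threshold
m = compute_metrics(pruned)
kernel = calibrate_kernel(13_000.0)          # p(13 km) = 0.05
res = node_importance(pruned, kernel)
print(m.n_links, round(m.link_density, 3), m.n_clusters)
print(res.to_dataframe().sort_values("rank").head(3))
```

prints

```
9707 0.558 1
  id       area_m2       dPC  rank
w086 137125.325448 23.904199     1
w019  71561.357096 13.886054     2
w089  65288.536580 10.096032     3
```

i.e. at a 13 km movement threshold this synthetic landscape keeps 9,707 of
its 17,391 potential links (L = 0.558) in one connected cluster, and the
most important waterhole is a large one whose removal would erase 23.9% of
the network's PC numerator. The same pipeline runs from the shell:

```sh
aguadanet simulate --seed 42 --out out/          # landscape CSV + GeoJSON
aguadanet sweep    --seed 42 --out out/          # 11 scenarios x 5 distances
aguadanet importance --seed 42 --out out/        # per-node dPC + aggregate rank
aguadanet habitat  --seed 42 --out out/          # buffer-union summaries
aguadanet report   --seed 42 --out out/          # everything + manifest.json
```

All commands accept `--config config.yaml` (scenario thresholds, distances,
kernel tail probability, buffer radii, input paths or synthetic settings,
seed); flags override config keys. Logs go to stderr, data to files; runs
with the same seed are byte-identical.

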