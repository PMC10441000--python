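# kgxplain

Knowledge-graph machine learning for explainable drug repurposing. The
package has two cooperating modules:

1. **Drug-repurposing prediction (DRP)** — unsupervised graph embeddings
   (attribute features from a pluggable text encoder, PCA-compressed, then a
   neighborhood-aggregating encoder trained with a random-walk
   negative-sampling objective) feed a 3-class random-forest classifier
   (*treat / not-treat / unknown*) over concatenated drug–disease embedding
   pairs. Evaluation uses replacement-candidate ranking (MRR / Hit@K) with
   drug-, disease-, combined- and random-subset protocols.
2. **Mechanism-of-action (MOA) path prediction** — an adversarial
   actor–critic reinforcement-learning agent walks the knowledge graph from
   a drug for a fixed number of steps (with a self-loop stay action and
   PageRank-pruned action spaces). It is guided by demonstration paths
   extracted from known drug–target interactions plus literature closeness
   (normalized Google distance), via a path discriminator and a meta-path
   discriminator whose log-odds shape the reward together with a discounted
   terminal reward from the DRP classifier. Candidate paths are scored with
   a decayed log-policy score and ranked against curated mechanism paths.

Everything runs at desk scale on synthetic knowledge graphs with planted
treatment structure (`kgxplain.synthetic_kg`), so the full pipeline is
exercisable end-to-end on one CPU in minutes — no downloads, no GPU.

The neural components (encoder, actor, critic, discriminators) are built on
a small internal reverse-mode autodiff over numpy (`kgxplain.autograd`,
`kgxplain.nn`); no deep-learning framework is required.

## Command-line interface

The `kgx` entry point chains the pipeline on TSV/JSON-lines artifacts:

```bash
kgx simulate --config synth.yaml --seed 3 --out fx/       # synthetic KG + manifest
kgx build-kg --nodes fx/nodes.tsv --edges fx/edges.tsv --out kg/
kgx ngd-filter --pubs fx/concept_pubs.tsv --pairs fx/pairs.tsv --out filtered.tsv
kgx make-pairs --sources synthetic=fx/pairs.tsv --kg kg/ --seed 0 --out pairs.tsv
kgx train-embeddings --kg kg/ --config emb.yaml --out emb/
kgx train-drp --embeddings emb/embeddings.tsv --pairs pairs.tsv --out drp/
kgx rank --embeddings emb/embeddings.tsv --pairs pairs.tsv --model drp/ \
    --mode random_subset --subset-size 1000 --repeats 10 --out ranks.tsv
kgx extract-demo-paths --kg kg/ --pairs fx/pairs.tsv \
    --targets fx/drug_targets.tsv --pubs fx/concept_pubs.tsv --out demo.jsonl
kgx train-moa --kg kg/ --embeddings emb/ --drp drp/ --demo demo.jsonl \
    --pairs pairs.tsv --config rl.yaml --out moa/
kgx predict-paths --moa moa/ --drug DRUG:0001 --disease DIS:0002 --top 10
kgx evaluate --task drp --ranks ranks.tsv
```

File formats: nodes/edges/pairs/targets as headered TSV, publication map as
long-format TSV with a `#total_pairs=N` comment line, paths as JSON-lines
(`{"nodes": [...], "predicates": [...]}`).

## Layout

```
src/kgxplain/
  kg_store.py        directed multigraph, loaders, customization filters, PageRank
  literature_ngd.py  publication co-occurrence NGD + literature filter
  pair_data.py       label merging, unknown-pair negative sampling, per-drug 8/1/1 split
  autograd.py, nn.py minimal numpy autodiff + MLP/batch-norm/embedding/Adam
  node_embeddings.py attribute encoder, PCA, walk corpus, graph-embedding training
  drp.py             pair features, 3-class forest, replacement ranking
  demo_paths.py      target-anchored demonstration-path extraction
  moa_rl.py          MDP, four subnetworks, reward shaping, multistage training
  path_eval.py       path enumeration/scoring/ranking, matching, metrics
  synthetic_kg.py    seeded synthetic KGs with planted mechanisms + manifest
  cli.py             the `kgx` command group
```
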