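# gpd — graph-transformer fixed-backbone protein sequence design

`gpd` addresses the inverse protein folding problem: given a fixed backbone
structure (the N/CA/C/O trace of one chain), generate amino-acid sequences
predicted to fold into it. It is aimed at protein engineers who want a
transparent, dependency-light implementation of a Graphormer-style design
model together with the evaluation metrics and virtual-screening filters
used to triage designed enzyme candidates.

## The model

The backbone is treated as a graph: one node per residue, an edge wherever
two Cα atoms lie within 12 Å. Node features are the φ/ψ dihedrals (sin/cos
encoded), an 8-class DSSP secondary-structure one-hot, the unnormalized
betweenness centrality C_b(k) = Σ_{i<j} g_ij(k)/g_ij on the contact graph,
a 22-token pre-designed-sequence channel (user constraints; all-zeros when
free) and a Gaussian noise block that widens the designed sequence space.
Edge features are SE(3)-invariant: the Cα–Cα distance, the unit
inter-residue direction expressed in the local residue frame
O = orthonormalized [CA→C, CA→N, CA→C × CA→N] (v_m = Oᵢᵀ·ΔCA/‖ΔCA‖), the
quaternion of the relative rotation q(OᵢᵀOⱼ), and the contact-graph
shortest-path length.

The encoder is a stack of six pre-LN Transformer blocks (10 heads,
feed-forward width 1024) whose attention scores carry an additive edge
bias:

    A_ij = (h_i W_Q)(h_j W_K)ᵀ / √d_K + C_att(i, j)

with C_att the mean of the embedded edge dimensions routed to the head;
from the second block on, node states flow back into the edge embedding.
A linear layer + softmax over C = 22 classes (20 amino acids, unknown,
padding) gives per-position probabilities; training minimizes mean
cross-entropy with Adam (lr 0.002, batch 64), revealing a random fraction
of each training sequence through the pre-design channel per step and
validating fully masked. The network is implemented in plain numpy with
hand-written gradients (checked against finite differences in the tests),
so no deep-learning framework is required.

Designed sequences are scored by recovery (fraction of positions matching
the native sequence), set diversity (one minus the mean pairwise fraction
of identical-or-BLOSUM62-similar positions), RMSD (raw or
Kabsch-superposed), composition statistics and a BLOSUM-style log-odds
confusion matrix. The screening module implements the enzyme-design
funnel: a non-polar substrate-pocket rule, radius of gyration, conserved-
site RMSD (< 1.5 Å), externally predicted pLDDT (> 80), net charge
(#Arg + #Lys − #Asp − #Glu), burial-weighted surface hydrophobicity, plus
trajectory summaries (dynamic cross-correlation matrix, hydrogen-bond
occupancy at 3.0 Å / 120° cutoffs). The conserved-position bookkeeping for
the CalB lipase case study (62 fixed sites including the S105/D187/H224
catalytic triad) is included.

## Worked example

Train the small configuration on five synthetic helix/loop proteins
(length 40) whose sequences are correlated with local structure, then
design sequences with three positions held fixed:

```python
import numpy as np, gpd
from gpd.design import TrainConfig, train, design, training_recovery, \
    _featurize_dataset
from gpd.metrics import recovery, diversity, composition_stats

data = gpd.make_toy_dataset(5, 40, seed=11)
cfg = gpd.ModelConfig.small()
state, hist = train(data, TrainConfig(epochs=300, batch_size=1, seed=3), cfg)

feats = _featurize_dataset(data, cfg.d_noise)
print(f"fresh-model masked loss : {hist['val_loss'][0]:.4f}")
print(f"final masked loss       : {hist['val_loss'][-1]:.4f}")
print(f"training-set recovery   : {training_recovery(feats, state, cfg):.3f}")

b, native = data[0]
out = design(b, state, n=20, model_cfg=cfg,
             fixed={4: "S", 17: "D", 33: "H"}, seed=7)
print(f"mean recovery vs native : "
      f"{np.mean([recovery(s, native) for s in out.sequences]):.3f}")
print(f"pairwise diversity      : {diversity(out):.3f}")
```

prints

```
fresh-model masked loss : 3.0924
final masked loss       : 0.1700
training-set recovery   : 0.965
mean recovery vs native : 0.871
pairwise diversity      : 0.068
```

The fresh model scores ln 22 ≈ 3.091 (uniform over 22 classes); after 300
epochs it recovers 96.5% of the training residues from structure alone,
and sampling with per-sequence noise yields a diverse constrained set in
which every output carries S/D/H at the fixed positions.

The same pipeline is scriptable from the shell:

```sh
gpd fixtures --kind helix --out fx
gpd design fx/helix.pdb --n 10 --fix "3:S" --seed 1 --out designs.fasta
gpd score designs.fasta native.fasta
gpd screen candidates.tsv --thresholds thresholds.json
```

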