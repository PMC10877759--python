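knn_k: 15
encoder: {embed_dim: 64, num_heads: 4, lambda_mix: 0.8, dropout: 0.3, alpha_init: 0.5,
  beta_init: 0.5, attention_scope: knn, transformer_block: parallel}
decoder:
  hidden_dims: [64, 32]
model: {interaction_dim: 64, neighbor_dim: 32, duplicate_interaction: true, use_transformer: true,
  use_ncf: true}
training:
  learning_rate: 0.0005
  dropout: 0.3
  focal_alpha: 0.5
  focal_gamma: 2.0
  loss_weights: [1.0, 1.0, 1.0, 1.0]
  epochs: 300
  patience: 30
  val_fraction: 0.1
  seed: 0
  lr_min: 5.0e-05
  lr_max: 0.0005
  cycle_len: 20
  ranking_margin: 1.0
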