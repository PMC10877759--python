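# Desk-scale configuration for the synthetic planted-structure dataset:
# fixed 500-epoch budget, early stopping disabled (validation splits at this
# data size are too small to give a usable stopping signal).
knn_k: 15
training:
  epochs: 500
  patience: null
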