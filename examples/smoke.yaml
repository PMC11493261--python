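# Minimal end-to-end smoke run: finishes in well under a minute on one CPU.
dataset:
  image_size: 16
  n_per_class_per_split: {train: 12, test: 12, validation: 12}
classifier:
  width: 8
  epochs: 3
attack:
  families: [fgsm, pgd]
  epsilons: [0.05, 0.1]
  n_iter: 3
denoiser:
  epochs: 3
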