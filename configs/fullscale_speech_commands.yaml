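# Full-scale replication recipe: ResNet-18 on a 35-word keyword corpus in
# the <root>/<word>/<file>.wav layout (e.g. the Speech Commands dataset),
# ~5,000 exemplars split 4,000 train / 1,000 test, 64-band log-Mel input,
# 10 epochs, 3 replicate seeds per arm, degradation sigma = 0.1 dataset SD.
#
# This configuration needs the external audio corpus and hours of CPU (or a
# GPU port) and is deliberately not exercised by the test suite.  Point
# data.wav_root at the corpus root, then:
#
#   speechmanifold run --config configs/fullscale_speech_commands.yaml \
#       --seed 0 --outdir runs/fullscale
#
# With ~143 files per word folder and train_fraction 0.8 the split is about
# 4,000/1,000; if your corpus copy is larger, downsample folders first.
data:
  source: wav_directory
  wav_root: /path/to/speech_commands
  n_classes: 35
  n_bands: 64
  n_frames: 98          # ~1 s of audio at the frontend defaults below
  train_fraction: 0.8
  frontend:
    n_mels: 64
    window_length: 400  # 25 ms at 16 kHz
    hop_length: 160     # 10 ms
    sample_rate: 16000.0
    fmin: 0.0
    fmax: null          # Nyquist
    log_floor: 1.0e-10
noise_sd_multiplier: 0.1
model_architecture: resnet18
training:
  epochs: 10
  batch_size: 32
  learning_rate: 0.01
  momentum: 0.9
  optimizer_name: sgd
  deterministic_mode: true
geometry:
  m_exemplars: 25       # <= test exemplars per word (~29)
  n_proj: 2000
  n_gaussian_samples: 150
  kappa: 0.0
  n_dichotomies: 200
  epoch_geometry: true
n_seeds: 3
conditions: [clean, degraded]
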