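# Full-scale saliency network: nine convolutional layers (first layer
# 96 filters of 7x7), two 2x2 max-pooling stages (total spatial
# downsampling by a factor of four), and one transposed-convolution layer
# (8x8, stride 4) restoring the 320x240 canvas resolution with a single
# output channel.
name: reference
input:
  width: 320
  height: 240
  channels: 3
layers:
  - {kind: conv, name: layer1, kernel: 7, channels: 96}
  - {kind: relu, name: layer1_relu}
  - {kind: maxpool, name: pool1, kernel: 2, stride: 2}
  - {kind: conv, name: layer2, kernel: 5, channels: 256}
  - {kind: relu, name: layer2_relu}
  - {kind: maxpool, name: pool2, kernel: 2, stride: 2}
  - {kind: conv, name: layer3, kernel: 3, channels: 512}
  - {kind: relu, name: layer3_relu}
  - {kind: conv, name: layer4, kernel: 5, channels: 512}
  - {kind: relu, name: layer4_relu}
  - {kind: conv, name: layer5, kernel: 5, channels: 512}
  - {kind: relu, name: layer5_relu}
  - {kind: conv, name: layer6, kernel: 7, channels: 512}
  - {kind: relu, name: layer6_relu}
  - {kind: conv, name: layer7, kernel: 11, channels: 256}
  - {kind: relu, name: layer7_relu}
  - {kind: conv, name: layer8, kernel: 11, channels: 128}
  - {kind: relu, name: layer8_relu}
  - {kind: conv, name: layer9, kernel: 13, channels: 32}
  - {kind: relu, name: layer9_relu}
  - {kind: deconv, name: deconv, kernel: 8, stride: 4, channels: 1}
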