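# Desk-scale test network: same layer-kind sequence as the reference
# architecture (nine conv, two pools, one deconv; total downsampling 4,
# output at canvas resolution) but a 32x24 canvas and <=16 channels so
# training and recording run in seconds on one CPU.
name: tiny
input:
  width: 32
  height: 24
  channels: 3
layers:
  - {kind: conv, name: layer1, kernel: 3, channels: 8}
  - {kind: relu, name: layer1_relu}
  - {kind: maxpool, name: pool1, kernel: 2, stride: 2}
  - {kind: conv, name: layer2, kernel: 3, channels: 12}
  - {kind: relu, name: layer2_relu}
  - {kind: maxpool, name: pool2, kernel: 2, stride: 2}
  - {kind: conv, name: layer3, kernel: 3, channels: 12}
  - {kind: relu, name: layer3_relu}
  - {kind: conv, name: layer4, kernel: 3, channels: 16}
  - {kind: relu, name: layer4_relu}
  - {kind: conv, name: layer5, kernel: 3, channels: 16}
  - {kind: relu, name: layer5_relu}
  - {kind: conv, name: layer6, kernel: 3, channels: 12}
  - {kind: relu, name: layer6_relu}
  - {kind: conv, name: layer7, kernel: 3, channels: 8}
  - {kind: relu, name: layer7_relu}
  - {kind: conv, name: layer8, kernel: 3, channels: 8}
  - {kind: relu, name: layer8_relu}
  - {kind: conv, name: layer9, kernel: 3, channels: 4}
  - {kind: relu, name: layer9_relu}
  - {kind: deconv, name: deconv, kernel: 8, stride: 4, channels: 1}
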