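# Frozen default FPM-Net architecture ("fpmnet-default").
# Builds deterministically; the parameter totals this profile pins are
# <= 2.45M with the feature-preserving block and <= 2.44M without it.
input_height: 256
input_width: 256
input_channels: 3
num_classes: 2
fdb_blocks: 4
fdb_channel_schedule: [64, 128, 256, 384]
convs_per_block: 2
kernel_size: 3
dilation_rate: 2
use_fpb: true
fpb_channels: 16
depthwise_separable_from_block: 2
pooling_ops: 3
bottleneck_channels: 2
fub_channel_schedule: [320, 160, 64]
fif_channels: 32
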