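"""Bundled reference validation-loss traces and degradation counts.

These are the desk-scale inputs to patience calibration: per-epoch test-loss
traces from fixed-activation CIFAR-10 trainings of VGG16 and DenseNet121
(three repeats each), first for from-scratch trainings of every candidate
activation, then for trainings continued from each repeat's best activation
with every remaining candidate.  The companion count tables give, for each
trace, the published longest run of consecutive epochs without a new best
validation loss; ``afcs.calibration`` re-derives them from the traces and
turns their averages into the default patience settings p0=3, p1=2.
"""

from __future__ import annotations

# activation order used throughout the count tables
COUNT_AFS = ("ReLU", "ELU", "SELU", "Mish", "SiLU", "GELU")

# (model, repeat, activation) -> per-epoch validation loss, epoch 1 first.
FIRST_SEGMENT_TRACES: dict[tuple[str, str, str], tuple[float, ...]] = {
    ('VGG16', 'Exp1', 'Tanh'): (2.3076,),
    ('VGG16', 'Exp1', 'ReLU'): (0.9476, 0.6696, 0.5962, 0.5256),
    ('VGG16', 'Exp1', 'ELU'): (1.0678, 0.6680, 0.5724, 0.5992, 0.5696, 0.5554),
    ('VGG16', 'Exp1', 'SELU'): (1.2563, 0.7820, 0.6139, 0.6085, 0.6102, 0.5163),
    ('VGG16', 'Exp1', 'Mish'): (1.2892, 0.8432, 0.6929, 0.6095, 0.6128, 0.5340),
    ('VGG16', 'Exp1', 'SiLU'): (1.1551, 0.8062, 0.6398, 0.6129, 0.5439),
    ('VGG16', 'Exp1', 'GELU'): (1.1570, 0.7725, 0.7045, 0.6445, 0.5598, 0.5436),
    ('VGG16', 'Exp2', 'Tanh'): (2.3142, 2.3071),
    ('VGG16', 'Exp2', 'ReLU'): (1.0733, 0.6606, 0.6901, 0.5445, 0.5327),
    ('VGG16', 'Exp2', 'ELU'): (0.9366, 0.7246, 0.5796, 0.5255, 0.6197, 0.5106),
    ('VGG16', 'Exp2', 'SELU'): (1.4203, 0.8865, 0.6664, 0.5771, 0.5706, 0.5274),
    ('VGG16', 'Exp2', 'Mish'): (1.2050, 0.8317, 0.5938, 0.5877, 0.5932, 0.5679),
    ('VGG16', 'Exp2', 'SiLU'): (1.2574, 0.7698, 0.6802, 0.5580, 0.5556),
    ('VGG16', 'Exp2', 'GELU'): (1.3257, 0.9488, 0.6997, 0.6504, 0.5919, 0.5578),
    ('VGG16', 'Exp3', 'Tanh'): (2.3181, 2.3079),
    ('VGG16', 'Exp3', 'ReLU'): (1.3439, 0.8153, 0.7513, 0.6177, 0.5600, 0.5151),
    ('VGG16', 'Exp3', 'ELU'): (2.3096, 2.3157, 2.3073, 1.3916, 0.7189, 0.6646, 0.5391, 0.5236),
    ('VGG16', 'Exp3', 'SELU'): (1.2635, 0.8118, 0.6305, 0.6437, 0.5747),
    ('VGG16', 'Exp3', 'Mish'): (1.2560, 0.7729, 0.6168, 0.5809, 0.5858, 0.5580),
    ('VGG16', 'Exp3', 'SiLU'): (1.2025, 0.7723, 0.6512, 0.5713),
    ('VGG16', 'Exp3', 'GELU'): (1.6888, 0.8539, 0.9304, 0.6721, 0.5833, 0.6320, 0.5170),
    ('DenseNet121', 'Exp1', 'Tanh'): (2.5334, 1.3031, 1.5998, 1.1421, 1.1080, 1.0704, 0.9837, 0.8963, 0.8924, 1.2865, 0.8584, 20.3810, 0.9130, 0.9475, 1.5578, 0.7754),
    ('DenseNet121', 'Exp1', 'ReLU'): (0.6554, 0.5978),
    ('DenseNet121', 'Exp1', 'ELU'): (1.5114, 1.1989, 1.2462, 0.8565, 0.9678, 0.8023, 0.7692, 0.8283, 0.7902, 0.7778, 0.6953),
    ('DenseNet121', 'Exp1', 'SELU'): (1.1965, 1.1150, 1.0469, 1.0753, 0.9509, 0.8480, 0.8905, 0.8551, 0.8649, 0.9231, 0.8685, 0.9441, 0.7886, 0.8488, 0.7172),
    ('DenseNet121', 'Exp1', 'Mish'): (1.1738, 1.0227, 0.8134, 1.1066, 0.9248, 0.6475),
    ('DenseNet121', 'Exp1', 'SiLU'): (1.1499, 0.9996, 0.9571, 0.7643, 1.0973, 0.7673, 0.7938, 0.7441, 0.8058, 0.7149, 0.6174),
    ('DenseNet121', 'Exp1', 'GELU'): (0.9080, 0.6984, 0.6139, 0.6911, 0.7137, 0.5965),
    ('DenseNet121', 'Exp2', 'Tanh'): (2.6434, 1.4907, 1.8102, 0.9409, 1.4932, 1.3614, 0.9439, 1.0116, 0.9864, 1.2859, 0.7728),
    ('DenseNet121', 'Exp2', 'ReLU'): (0.6864, 0.6845, 0.6161),
    ('DenseNet121', 'Exp2', 'ELU'): (1.2152, 1.0475, 0.8702, 1.0633, 0.9105, 0.7997, 0.8416, 0.8869, 0.9702, 0.7945, 0.7792, 1.0680, 0.7520, 0.7260),
    ('DenseNet121', 'Exp2', 'SELU'): (1.2862, 1.0604, 1.1703, 1.1219, 1.0914, 0.9500, 1.0224, 1.2598, 1.0666, 1.2473, 0.8475, 0.7670),
    ('DenseNet121', 'Exp2', 'Mish'): (1.3581, 1.4940, 0.7974, 0.8704, 0.7391, 0.7348, 0.6762, 0.7274, 0.7168, 0.7997, 0.6685),
    ('DenseNet121', 'Exp2', 'SiLU'): (1.1517, 1.1341, 0.8132, 0.8092, 0.7236, 0.7522, 0.7218, 0.7383, 0.7116, 0.6661, 0.7161, 0.6738, 0.6274),
    ('DenseNet121', 'Exp2', 'GELU'): (0.8766, 0.8051, 0.6477, 0.6355, 0.8993, 0.5716),
    ('DenseNet121', 'Exp3', 'Tanh'): (2.8821, 1.2687, 1.1558, 1.1121, 0.9807, 0.9404, 1.1520, 0.9789, 0.9592, 0.8842, 1.2925, 0.7164),
    ('DenseNet121', 'Exp3', 'ReLU'): (0.6683, 1.0291, 0.5604),
    ('DenseNet121', 'Exp3', 'ELU'): (1.4735, 0.9248, 0.8414, 0.8957, 1.0537, 0.7695, 1.1104, 0.8887, 0.8042, 0.7549, 0.7156, 0.8619, 1.0142, 0.7758, 0.6857),
    ('DenseNet121', 'Exp3', 'SELU'): (1.2436, 1.1282, 1.0731, 1.1002, 0.9099, 0.8878, 0.8715, 0.8372, 0.9499, 0.8418, 1.1430, 0.9685, 0.9562, 1.1994, 0.8176, 0.9022, 0.9555, 0.8060),
    ('DenseNet121', 'Exp3', 'Mish'): (1.0554, 1.1075, 0.7743, 0.8894, 0.6880, 0.6593, 0.8545, 0.5865),
    ('DenseNet121', 'Exp3', 'SiLU'): (1.0850, 0.9101, 0.8047, 0.7906, 0.7124, 0.7021, 0.7681, 0.7868, 0.6442),
    ('DenseNet121', 'Exp3', 'GELU'): (0.8528, 0.9093, 0.8000, 0.7144, 0.6606, 0.6444, 0.6788, 0.6399),
}

# (model, repeat, best activation of the finished segment, next activation)
# -> per-epoch validation loss of the continued training.
NEXT_SEGMENT_TRACES: dict[tuple[str, str, str, str], tuple[float, ...]] = {
    ('VGG16', 'Exp1', 'SELU', 'ReLU'): (0.5176,),
    ('VGG16', 'Exp1', 'SELU', 'ELU'): (0.5686, 0.5863, 0.5659),
    ('VGG16', 'Exp1', 'SELU', 'Mish'): (0.5154,),
    ('VGG16', 'Exp1', 'SELU', 'SiLU'): (0.5488,),
    ('VGG16', 'Exp1', 'SELU', 'GELU'): (0.5974,),
    ('VGG16', 'Exp1', 'ReLU', 'ELU'): (0.5669, 0.5193),
    ('VGG16', 'Exp1', 'ReLU', 'SELU'): (0.8879, 0.6527, 0.6220, 0.5375),
    ('VGG16', 'Exp1', 'ReLU', 'Mish'): (0.5360,),
    ('VGG16', 'Exp1', 'ReLU', 'SiLU'): (0.5024,),
    ('VGG16', 'Exp1', 'ReLU', 'GELU'): (0.5180,),
    ('VGG16', 'Exp1', 'Mish', 'ReLU'): (0.5685,),
    ('VGG16', 'Exp1', 'Mish', 'ELU'): (0.6889, 0.6410, 0.5883),
    ('VGG16', 'Exp1', 'Mish', 'SELU'): (0.7069, 0.5970),
    ('VGG16', 'Exp1', 'Mish', 'SiLU'): (0.5997,),
    ('VGG16', 'Exp1', 'Mish', 'GELU'): (0.5727,),
    ('VGG16', 'Exp2', 'ELU', 'ReLU'): (0.5168,),
    ('VGG16', 'Exp2', 'ELU', 'SELU'): (0.5886,),
    ('VGG16', 'Exp2', 'ELU', 'Mish'): (0.5549,),
    ('VGG16', 'Exp2', 'ELU', 'SiLU'): (0.5565, 0.5424),
    ('VGG16', 'Exp2', 'ELU', 'GELU'): (0.5648,),
    ('VGG16', 'Exp2', 'SELU', 'ReLU'): (0.5955, 0.5555),
    ('VGG16', 'Exp2', 'SELU', 'ELU'): (0.5296,),
    ('VGG16', 'Exp2', 'SELU', 'Mish'): (0.6120, 0.5665),
    ('VGG16', 'Exp2', 'SELU', 'SiLU'): (0.5394, 0.5379),
    ('VGG16', 'Exp2', 'SELU', 'GELU'): (0.5688, 0.5490),
    ('VGG16', 'Exp2', 'ReLU', 'ELU'): (0.7453, 0.5835, 0.5711),
    ('VGG16', 'Exp2', 'ReLU', 'SELU'): (0.9466, 0.6856, 0.5991, 0.5508),
    ('VGG16', 'Exp2', 'ReLU', 'Mish'): (0.5607,),
    ('VGG16', 'Exp2', 'ReLU', 'SiLU'): (0.5521,),
    ('VGG16', 'Exp2', 'ReLU', 'GELU'): (0.5671,),
    ('VGG16', 'Exp3', 'ReLU', 'ELU'): (0.6359, 0.5564),
    ('VGG16', 'Exp3', 'ReLU', 'SELU'): (0.6902, 0.5660),
    ('VGG16', 'Exp3', 'ReLU', 'Mish'): (0.5166,),
    ('VGG16', 'Exp3', 'ReLU', 'SiLU'): (0.5393, 0.5208),
    ('VGG16', 'Exp3', 'ReLU', 'GELU'): (0.5562,),
    ('VGG16', 'Exp3', 'GELU', 'ReLU'): (0.5698,),
    ('VGG16', 'Exp3', 'GELU', 'ELU'): (0.8151, 0.5771, 0.5500),
    ('VGG16', 'Exp3', 'GELU', 'SELU'): (1.0327, 0.6736, 0.6185, 0.5921),
    ('VGG16', 'Exp3', 'GELU', 'Mish'): (0.5688, 0.5681),
    ('VGG16', 'Exp3', 'GELU', 'SiLU'): (0.5495,),
    ('VGG16', 'Exp3', 'ELU', 'ReLU'): (0.5722, 0.5171),
    ('VGG16', 'Exp3', 'ELU', 'SELU'): (0.5233,),
    ('VGG16', 'Exp3', 'ELU', 'Mish'): (0.5318,),
    ('VGG16', 'Exp3', 'ELU', 'SiLU'): (0.5265,),
    ('VGG16', 'Exp3', 'ELU', 'GELU'): (0.5046,),
    ('DenseNet121', 'Exp1', 'GELU', 'ReLU'): (0.5478,),
    ('DenseNet121', 'Exp1', 'GELU', 'ELU'): (0.9620, 0.7391, 0.8254, 1.0896, 0.7031),
    ('DenseNet121', 'Exp1', 'GELU', 'SELU'): (1.2328, 1.1520, 1.3142, 1.0417, 1.2832, 1.2325, 1.5440, 0.8618),
    ('DenseNet121', 'Exp1', 'GELU', 'Mish'): (0.9561, 0.7870, 0.6893, 0.7205, 0.6803),
    ('DenseNet121', 'Exp1', 'GELU', 'SiLU'): (0.6372,),
    ('DenseNet121', 'Exp1', 'ReLU', 'ELU'): (1.5544, 0.9110, 0.9521, 1.1389, 0.9409, 0.9092, 0.8348, 0.8329, 0.7013, 0.8792, 0.8068, 0.8731, 0.7015, 0.6589),
    ('DenseNet121', 'Exp1', 'ReLU', 'SELU'): (1.2104, 1.0741, 1.0381, 1.2686, 1.2387, 0.9237, 1.0289, 0.8830, 1.0159, 0.7960),
    ('DenseNet121', 'Exp1', 'ReLU', 'Mish'): (0.9347, 0.7624, 0.7525, 1.0301, 0.8243, 0.6854, 0.7646, 0.6800, 0.6325),
    ('DenseNet121', 'Exp1', 'ReLU', 'SiLU'): (0.8831, 0.7925, 0.6902, 0.6127, 0.7614, 0.7430, 0.6335, 0.6071, 0.5949),
    ('DenseNet121', 'Exp1', 'ReLU', 'GELU'): (0.8520, 0.7353, 0.6069, 0.7015, 0.6703, 0.5824),
    ('DenseNet121', 'Exp1', 'SiLU', 'ReLU'): (0.6180,),
    ('DenseNet121', 'Exp1', 'SiLU', 'ELU'): (1.1109, 0.7586, 0.6890),
    ('DenseNet121', 'Exp1', 'SiLU', 'SELU'): (1.7046, 1.2093, 0.9131),
    ('DenseNet121', 'Exp1', 'SiLU', 'Mish'): (0.7340, 0.7088),
    ('DenseNet121', 'Exp1', 'SiLU', 'GELU'): (0.6514,),
    ('DenseNet121', 'Exp2', 'GELU', 'ReLU'): (0.5539,),
    ('DenseNet121', 'Exp2', 'GELU', 'ELU'): (0.8230, 1.0572, 0.8220, 0.8454, 0.7590, 0.7906, 0.7254),
    ('DenseNet121', 'Exp2', 'GELU', 'SELU'): (1.3235, 1.1054, 1.0143, 0.9445, 0.8853, 0.9024, 0.9238, 1.1919, 1.1035, 0.8324),
    ('DenseNet121', 'Exp2', 'GELU', 'Mish'): (0.7502, 0.6783, 0.6193),
    ('DenseNet121', 'Exp2', 'GELU', 'SiLU'): (0.6129,),
    ('DenseNet121', 'Exp2', 'ReLU', 'ELU'): (1.0134, 0.9379, 1.0422, 0.9784, 0.8998, 0.8033, 0.8312, 0.7211),
    ('DenseNet121', 'Exp2', 'ReLU', 'SELU'): (1.2213, 1.1288, 0.9406, 1.0536, 1.1468, 0.9460, 0.8926, 0.9610, 0.8678),
    ('DenseNet121', 'Exp2', 'ReLU', 'Mish'): (0.9434, 0.7861, 0.6726, 0.9586, 0.7218, 0.7172, 0.8329, 0.6197),
    ('DenseNet121', 'Exp2', 'ReLU', 'SiLU'): (0.8702, 0.8505, 0.9180, 0.6715, 0.5984),
    ('DenseNet121', 'Exp2', 'ReLU', 'GELU'): (0.9008, 0.7791, 0.6313, 0.6604, 0.7107, 0.6131, 0.6058, 0.5496),
    ('DenseNet121', 'Exp2', 'SiLU', 'ReLU'): (0.6232,),
    ('DenseNet121', 'Exp2', 'SiLU', 'ELU'): (0.9390, 0.8063, 1.0008, 0.7552, 0.8774, 0.8153, 0.7441),
    ('DenseNet121', 'Exp2', 'SiLU', 'SELU'): (1.5974, 1.1322, 0.9104, 0.9664, 1.0150, 1.1679, 0.8454),
    ('DenseNet121', 'Exp2', 'SiLU', 'Mish'): (0.7148,),
    ('DenseNet121', 'Exp2', 'SiLU', 'GELU'): (0.6366,),
    ('DenseNet121', 'Exp3', 'ReLU', 'ELU'): (1.1103, 1.3042, 0.8980, 0.8322, 0.8283, 1.0211, 0.8523, 0.8341, 0.8244, 0.8018, 0.6888, 0.7590, 0.6685),
    ('DenseNet121', 'Exp3', 'ReLU', 'SELU'): (1.1455, 1.1690, 1.1342, 0.9823, 0.9458, 1.3660, 0.9618, 1.2932, 0.9192, 0.7769),
    ('DenseNet121', 'Exp3', 'ReLU', 'Mish'): (0.9927, 0.8607, 0.7389, 0.6869, 0.6260, 0.6776, 0.6410, 0.7156, 0.8070, 0.6258),
    ('DenseNet121', 'Exp3', 'ReLU', 'SiLU'): (1.1415, 0.8905, 0.6987, 0.6999, 0.7668, 0.5890),
    ('DenseNet121', 'Exp3', 'ReLU', 'GELU'): (0.9124, 0.6170, 0.7598, 0.6880, 0.5713),
    ('DenseNet121', 'Exp3', 'Mish', 'ReLU'): (0.5551,),
    ('DenseNet121', 'Exp3', 'Mish', 'ELU'): (0.8781, 0.9072, 0.8157, 0.7380),
    ('DenseNet121', 'Exp3', 'Mish', 'SELU'): (0.9893, 0.9175),
    ('DenseNet121', 'Exp3', 'Mish', 'SiLU'): (0.6514,),
    ('DenseNet121', 'Exp3', 'Mish', 'GELU'): (0.6946, 0.6533),
    ('DenseNet121', 'Exp3', 'GELU', 'ReLU'): (0.5971,),
    ('DenseNet121', 'Exp3', 'GELU', 'ELU'): (0.8531, 0.8778, 0.9276, 0.8790, 0.9445, 0.7341),
    ('DenseNet121', 'Exp3', 'GELU', 'SELU'): (1.3561, 1.0365),
    ('DenseNet121', 'Exp3', 'GELU', 'Mish'): (0.6342,),
    ('DenseNet121', 'Exp3', 'GELU', 'SiLU'): (0.9523, 0.7361, 0.7168, 0.7327, 0.7413, 0.6974),
}

# published longest-degradation-run counts for the first-segment traces
# (Tanh is excluded: it was dropped from the candidate list for not learning).
FIRST_SEGMENT_COUNTS: dict[tuple[str, str, str], int] = {
    ('VGG16', 'Exp1', 'ReLU'): 0,
    ('VGG16', 'Exp1', 'ELU'): 1,
    ('VGG16', 'Exp1', 'SELU'): 1,
    ('VGG16', 'Exp1', 'Mish'): 1,
    ('VGG16', 'Exp1', 'SiLU'): 0,
    ('VGG16', 'Exp1', 'GELU'): 0,
    ('VGG16', 'Exp2', 'ReLU'): 1,
    ('VGG16', 'Exp2', 'ELU'): 1,
    ('VGG16', 'Exp2', 'SELU'): 0,
    ('VGG16', 'Exp2', 'Mish'): 1,
    ('VGG16', 'Exp2', 'SiLU'): 0,
    ('VGG16', 'Exp2', 'GELU'): 0,
    ('VGG16', 'Exp3', 'ReLU'): 0,
    ('VGG16', 'Exp3', 'ELU'): 1,
    ('VGG16', 'Exp3', 'SELU'): 1,
    ('VGG16', 'Exp3', 'Mish'): 1,
    ('VGG16', 'Exp3', 'SiLU'): 0,
    ('VGG16', 'Exp3', 'GELU'): 1,
    ('DenseNet121', 'Exp1', 'ReLU'): 0,
    ('DenseNet121', 'Exp1', 'ELU'): 3,
    ('DenseNet121', 'Exp1', 'SELU'): 6,
    ('DenseNet121', 'Exp1', 'Mish'): 2,
    ('DenseNet121', 'Exp1', 'SiLU'): 3,
    ('DenseNet121', 'Exp1', 'GELU'): 2,
    ('DenseNet121', 'Exp2', 'ReLU'): 0,
    ('DenseNet121', 'Exp2', 'ELU'): 3,
    ('DenseNet121', 'Exp2', 'SELU'): 4,
    ('DenseNet121', 'Exp2', 'Mish'): 3,
    ('DenseNet121', 'Exp2', 'SiLU'): 2,
    ('DenseNet121', 'Exp2', 'GELU'): 1,
    ('DenseNet121', 'Exp3', 'ReLU'): 1,
    ('DenseNet121', 'Exp3', 'ELU'): 3,
    ('DenseNet121', 'Exp3', 'SELU'): 6,
    ('DenseNet121', 'Exp3', 'Mish'): 1,
    ('DenseNet121', 'Exp3', 'SiLU'): 2,
    ('DenseNet121', 'Exp3', 'GELU'): 1,
}

# published longest-degradation-run counts for the continued-segment traces.
NEXT_SEGMENT_COUNTS: dict[tuple[str, str, str, str], int] = {
    ('VGG16', 'Exp1', 'SELU', 'ReLU'): 0,
    ('VGG16', 'Exp1', 'SELU', 'ELU'): 1,
    ('VGG16', 'Exp1', 'SELU', 'Mish'): 0,
    ('VGG16', 'Exp1', 'SELU', 'SiLU'): 0,
    ('VGG16', 'Exp1', 'SELU', 'GELU'): 0,
    ('VGG16', 'Exp1', 'ReLU', 'ELU'): 0,
    ('VGG16', 'Exp1', 'ReLU', 'SELU'): 0,
    ('VGG16', 'Exp1', 'ReLU', 'Mish'): 0,
    ('VGG16', 'Exp1', 'ReLU', 'SiLU'): 0,
    ('VGG16', 'Exp1', 'ReLU', 'GELU'): 0,
    ('VGG16', 'Exp1', 'Mish', 'ReLU'): 0,
    ('VGG16', 'Exp1', 'Mish', 'ELU'): 0,
    ('VGG16', 'Exp1', 'Mish', 'SELU'): 0,
    ('VGG16', 'Exp1', 'Mish', 'SiLU'): 0,
    ('VGG16', 'Exp1', 'Mish', 'GELU'): 0,
    ('VGG16', 'Exp2', 'ELU', 'ReLU'): 0,
    ('VGG16', 'Exp2', 'ELU', 'SELU'): 0,
    ('VGG16', 'Exp2', 'ELU', 'Mish'): 0,
    ('VGG16', 'Exp2', 'ELU', 'SiLU'): 0,
    ('VGG16', 'Exp2', 'ELU', 'GELU'): 0,
    ('VGG16', 'Exp2', 'SELU', 'ReLU'): 0,
    ('VGG16', 'Exp2', 'SELU', 'ELU'): 0,
    ('VGG16', 'Exp2', 'SELU', 'Mish'): 0,
    ('VGG16', 'Exp2', 'SELU', 'SiLU'): 0,
    ('VGG16', 'Exp2', 'SELU', 'GELU'): 0,
    ('VGG16', 'Exp2', 'ReLU', 'ELU'): 0,
    ('VGG16', 'Exp2', 'ReLU', 'SELU'): 0,
    ('VGG16', 'Exp2', 'ReLU', 'Mish'): 0,
    ('VGG16', 'Exp2', 'ReLU', 'SiLU'): 0,
    ('VGG16', 'Exp2', 'ReLU', 'GELU'): 0,
    ('VGG16', 'Exp3', 'ReLU', 'ELU'): 0,
    ('VGG16', 'Exp3', 'ReLU', 'SELU'): 0,
    ('VGG16', 'Exp3', 'ReLU', 'Mish'): 0,
    ('VGG16', 'Exp3', 'ReLU', 'SiLU'): 0,
    ('VGG16', 'Exp3', 'ReLU', 'GELU'): 0,
    ('VGG16', 'Exp3', 'GELU', 'ReLU'): 0,
    ('VGG16', 'Exp3', 'GELU', 'ELU'): 0,
    ('VGG16', 'Exp3', 'GELU', 'SELU'): 0,
    ('VGG16', 'Exp3', 'GELU', 'Mish'): 0,
    ('VGG16', 'Exp3', 'GELU', 'SiLU'): 0,
    ('VGG16', 'Exp3', 'ELU', 'ReLU'): 0,
    ('VGG16', 'Exp3', 'ELU', 'SELU'): 0,
    ('VGG16', 'Exp3', 'ELU', 'Mish'): 0,
    ('VGG16', 'Exp3', 'ELU', 'SiLU'): 0,
    ('VGG16', 'Exp3', 'ELU', 'GELU'): 0,
    ('DenseNet121', 'Exp1', 'GELU', 'ReLU'): 0,
    ('DenseNet121', 'Exp1', 'GELU', 'ELU'): 2,
    ('DenseNet121', 'Exp1', 'GELU', 'SELU'): 3,
    ('DenseNet121', 'Exp1', 'GELU', 'Mish'): 1,
    ('DenseNet121', 'Exp1', 'GELU', 'SiLU'): 0,
    ('DenseNet121', 'Exp1', 'ReLU', 'ELU'): 4,
    ('DenseNet121', 'Exp1', 'ReLU', 'SELU'): 2,
    ('DenseNet121', 'Exp1', 'ReLU', 'Mish'): 2,
    ('DenseNet121', 'Exp1', 'ReLU', 'SiLU'): 3,
    ('DenseNet121', 'Exp1', 'ReLU', 'GELU'): 2,
    ('DenseNet121', 'Exp1', 'SiLU', 'ReLU'): 0,
    ('DenseNet121', 'Exp1', 'SiLU', 'ELU'): 0,
    ('DenseNet121', 'Exp1', 'SiLU', 'SELU'): 0,
    ('DenseNet121', 'Exp1', 'SiLU', 'Mish'): 0,
    ('DenseNet121', 'Exp1', 'SiLU', 'GELU'): 0,
    ('DenseNet121', 'Exp2', 'GELU', 'ReLU'): 0,
    ('DenseNet121', 'Exp2', 'GELU', 'ELU'): 1,
    ('DenseNet121', 'Exp2', 'GELU', 'SELU'): 4,
    ('DenseNet121', 'Exp2', 'GELU', 'Mish'): 0,
    ('DenseNet121', 'Exp2', 'GELU', 'SiLU'): 0,
    ('DenseNet121', 'Exp2', 'ReLU', 'ELU'): 2,
    ('DenseNet121', 'Exp2', 'ReLU', 'SELU'): 3,
    ('DenseNet121', 'Exp2', 'ReLU', 'Mish'): 4,
    ('DenseNet121', 'Exp2', 'ReLU', 'SiLU'): 1,
    ('DenseNet121', 'Exp2', 'ReLU', 'GELU'): 2,
    ('DenseNet121', 'Exp2', 'SiLU', 'ReLU'): 0,
    ('DenseNet121', 'Exp2', 'SiLU', 'ELU'): 2,
    ('DenseNet121', 'Exp2', 'SiLU', 'SELU'): 3,
    ('DenseNet121', 'Exp2', 'SiLU', 'Mish'): 0,
    ('DenseNet121', 'Exp2', 'SiLU', 'GELU'): 0,
    ('DenseNet121', 'Exp3', 'ReLU', 'ELU'): 3,
    ('DenseNet121', 'Exp3', 'ReLU', 'SELU'): 3,
    ('DenseNet121', 'Exp3', 'ReLU', 'Mish'): 4,
    ('DenseNet121', 'Exp3', 'ReLU', 'SiLU'): 2,
    ('DenseNet121', 'Exp3', 'ReLU', 'GELU'): 2,
    ('DenseNet121', 'Exp3', 'Mish', 'ReLU'): 0,
    ('DenseNet121', 'Exp3', 'Mish', 'ELU'): 1,
    ('DenseNet121', 'Exp3', 'Mish', 'SELU'): 0,
    ('DenseNet121', 'Exp3', 'Mish', 'SiLU'): 0,
    ('DenseNet121', 'Exp3', 'Mish', 'GELU'): 0,
    ('DenseNet121', 'Exp3', 'GELU', 'ReLU'): 0,
    ('DenseNet121', 'Exp3', 'GELU', 'ELU'): 4,
    ('DenseNet121', 'Exp3', 'GELU', 'SELU'): 0,
    ('DenseNet121', 'Exp3', 'GELU', 'Mish'): 0,
    ('DenseNet121', 'Exp3', 'GELU', 'SiLU'): 2,
}

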