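"""VGG19 and ResNet34 as complexity-calibration references.

These are instantiated only to cross-check the parameter/MAC accountant
against their widely printed budgets (143.67M / 19.63G and 22M / 3.7G at
224x224 with 1000-class heads); they are never trained here, so they default
to zero-initialized weights for cheap construction.
"""

from __future__ import annotations


from . import nn
from .nn import functional as F
from .nn.autodiff import Tensor

__all__ = ["vgg19", "resnet34"]

_VGG19_PLAN = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
               512, 512, 512, 512, "M", 512, 512, 512, 512, "M"]


class _VGG(nn.Module):
    def __init__(self, num_classes: int = 1000):
        super().__init__()
        layers: list[nn.Module] = []
        in_ch = 3
        for item in _VGG19_PLAN:
            if item == "M":
                layers.append(nn.MaxPool2d(2, 2))
            else:
                layers.append(nn.Conv2d(in_ch, item, 3, padding=1, init="zeros"))
                layers.append(nn.ReLU())
                in_ch = item
        self.features = nn.Sequential(*layers)
        self.classifier = nn.Sequential(
            nn.Linear(512 * 7 * 7, 4096, init="zeros"),
            nn.ReLU(),
            nn.Linear(4096, 4096, init="zeros"),
            nn.ReLU(),
            nn.Linear(4096, num_classes, init="zeros"),
        )

    def forward(self, x: Tensor) -> Tensor:
        x = self.features(x)
        x = x.reshape((x.shape[0], -1))
        return self.classifier(x)


def vgg19(num_classes: int = 1000) -> _VGG:
    """Plain (no batch-norm) VGG19 with the standard 4096-4096 classifier."""
    return _VGG(num_classes)


class _BasicBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                               bias=False, init="zeros")
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False, init="zeros")
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.short_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride,
                                        bias=False, init="zeros")
            self.short_bn = nn.BatchNorm2d(out_ch)
        else:
            self.short_conv = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(F.relu(self.bn1(self.conv1(x)))))
        identity = x if self.short_conv is None else self.short_bn(self.short_conv(x))
        return F.relu(out + identity)


class _ResNet(nn.Module):
    def __init__(self, blocks_per_stage=(3, 4, 6, 3), num_classes: int = 1000):
        super().__init__()
        self.conv1 = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False, init="zeros")
        self.bn1 = nn.BatchNorm2d(64)
        self.maxpool = nn.MaxPool2d(3, 2, padding=1)
        stages = []
        in_ch = 64
        for i, (n, out_ch) in enumerate(zip(blocks_per_stage, (64, 128, 256, 512))):
            for j in range(n):
                stride = 2 if (i > 0 and j == 0) else 1
                stages.append(_BasicBlock(in_ch, out_ch, stride))
                in_ch = out_ch
        self.stages = nn.Sequential(*stages)
        self.fc = nn.Linear(512, num_classes, init="zeros")

    def forward(self, x: Tensor) -> Tensor:
        x = self.maxpool(F.relu(self.bn1(self.conv1(x))))
        x = self.stages(x)
        x = x.mean(axis=(2, 3))
        return self.fc(x)


def resnet34(num_classes: int = 1000) -> _ResNet:
    """Standard ResNet-34 (basic blocks, 1x1 strided shortcut projections)."""
    return _ResNet((3, 4, 6, 3), num_classes)
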