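# synthetic placeholder single-copy marker universe (191 IDs)
# superset of the 104-ID placeholder universe
scg_001
scg_002
scg_003
scg_004
scg_005
scg_006
scg_007
scg_008
scg_009
scg_010
scg_011
scg_012
scg_013
scg_014
scg_015
scg_016
scg_017
scg_018
scg_019
scg_020
scg_021
scg_022
scg_023
scg_024
scg_025
scg_026
scg_027
scg_028
scg_029
scg_030
scg_031
scg_032
scg_033
scg_034
scg_035
scg_036
scg_037
scg_038
scg_039
scg_040
scg_041
scg_042
scg_043
scg_044
scg_045
scg_046
scg_047
scg_048
scg_049
scg_050
scg_051
scg_052
scg_053
scg_054
scg_055
scg_056
scg_057
scg_058
scg_059
scg_060
scg_061
scg_062
scg_063
scg_064
scg_065
scg_066
scg_067
scg_068
scg_069
scg_070
scg_071
scg_072
scg_073
scg_074
scg_075
scg_076
scg_077
scg_078
scg_079
scg_080
scg_081
scg_082
scg_083
scg_084
scg_085
scg_086
scg_087
scg_088
scg_089
scg_090
scg_091
scg_092
scg_093
scg_094
scg_095
scg_096
scg_097
scg_098
scg_099
scg_100
scg_101
scg_102
scg_103
scg_104
scg_105
scg_106
scg_107
scg_108
scg_109
scg_110
scg_111
scg_112
scg_113
scg_114
scg_115
scg_116
scg_117
scg_118
scg_119
scg_120
scg_121
scg_122
scg_123
scg_124
scg_125
scg_126
scg_127
scg_128
scg_129
scg_130
scg_131
scg_132
scg_133
scg_134
scg_135
scg_136
scg_137
scg_138
scg_139
scg_140
scg_141
scg_142
scg_143
scg_144
scg_145
scg_146
scg_147
scg_148
scg_149
scg_150
scg_151
scg_152
scg_153
scg_154
scg_155
scg_156
scg_157
scg_158
scg_159
scg_160
scg_161
scg_162
scg_163
scg_164
scg_165
scg_166
scg_167
scg_168
scg_169
scg_170
scg_171
scg_172
scg_173
scg_174
scg_175
scg_176
scg_177
scg_178
scg_179
scg_180
scg_181
scg_182
scg_183
scg_184
scg_185
scg_186
scg_187
scg_188
scg_189
scg_190
scg_191
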