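# overlay render golden; shape (16,16,3) uint8
128 128 128
126 125 125
125 123 123
125 121 121
126 119 119
127 117 117
129 115 115
132 113 113
136 110 110
140 108 108
145 106 106
151 104 104
153 107 102
155 109 100
157 114 98
159 119 96
126 125 125
125 123 123
125 121 121
126 119 119
127 117 117
129 115 115
132 113 113
136 110 110
140 108 108
145 106 106
151 104 104
153 107 102
155 109 100
157 114 98
159 119 96
162 124 94
125 123 123
125 121 121
126 119 119
127 117 117
129 115 115
132 113 113
136 110 110
140 108 108
145 106 106
151 104 104
153 107 102
155 109 100
157 114 98
159 119 96
162 124 94
164 130 91
125 121 121
126 119 119
127 117 117
129 115 115
132 113 113
136 110 110
140 108 108
145 106 106
151 104 104
153 107 102
155 109 100
157 114 98
159 119 96
162 124 94
164 130 91
166 136 89
126 119 119
127 117 117
129 115 115
132 113 113
136 110 110
140 108 108
145 106 106
151 104 104
153 107 102
155 109 100
157 114 98
159 119 96
162 124 94
164 130 91
166 136 89
168 144 87
127 117 117
129 115 115
132 113 113
136 110 110
140 108 108
145 106 106
151 104 104
153 107 102
155 109 100
157 114 98
159 119 96
162 124 94
164 130 91
166 136 89
168 144 87
170 152 85
129 115 115
132 113 113
136 110 110
140 108 108
145 106 106
151 104 104
153 107 102
155 109 100
157 114 98
159 119 96
162 124 94
164 130 91
166 136 89
168 144 87
170 152 85
172 162 83
132 113 113
136 110 110
140 108 108
145 106 106
151 104 104
153 107 102
155 109 100
157 114 98
159 119 96
162 124 94
164 130 91
166 136 89
168 144 87
170 152 85
172 162 83
174 171 81
136 110 110
140 108 108
145 106 106
151 104 104
153 107 102
155 109 100
157 114 98
159 119 96
162 124 94
164 130 91
166 136 89
168 144 87
170 152 85
172 162 83
174 171 81
176 176 87
140 108 108
145 106 106
151 104 104
153 107 102
155 109 100
157 114 98
159 119 96
162 124 94
164 130 91
166 136 89
168 144 87
170 152 85
172 162 83
174 171 81
176 176 87
178 178 98
145 106 106
151 104 104
153 107 102
155 109 100
157 114 98
159 119 96
162 124 94
164 130 91
166 136 89
168 144 87
170 152 85
172 162 83
174 171 81
176 176 87
0 255 51
0 255 51
151 104 104
153 107 102
155 109 100
157 114 98
159 119 96
162 124 94
164 130 91
166 136 89
168 144 87
170 152 85
172 162 83
174 171 81
176 176 87
178 178 98
0 255 51
183 183 125
153 107 102
155 109 100
157 114 98
159 119 96
162 124 94
164 130 91
166 136 89
168 144 87
170 152 85
172 162 83
174 171 81
176 176 87
0 255 51
0 255 51
183 183 125
185 185 141
155 109 100
157 114 98
159 119 96
162 124 94
164 130 91
166 136 89
168 144 87
170 152 85
172 162 83
174 171 81
176 176 87
178 178 98
0 255 51
183 183 125
185 185 141
187 187 156
157 114 98
159 119 96
162 124 94
164 130 91
166 136 89
168 144 87
170 152 85
172 162 83
174 171 81
176 176 87
0 255 51
0 255 51
183 183 125
185 185 141
187 187 156
189 189 174
159 119 96
162 124 94
164 130 91
166 136 89
168 144 87
170 152 85
172 162 83
174 171 81
176 176 87
178 178 98
0 255 51
183 183 125
185 185 141
187 187 156
189 189 174
191 191 191
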