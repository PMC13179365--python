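name,parent,round,mutations
PHL7,,0,
L93F,PHL7,0,L93F
Q95G,PHL7,0,Q95G
Q95Y,PHL7,0,Q95Y
Q175E,PHL7,0,Q175E
L210T,PHL7,0,L210T
D233K,PHL7,0,D233K
L93F/Q95G,PHL7,0,L93F;Q95G
L93F/Q95Y,PHL7,0,L93F;Q95Y
L93F/L210T,PHL7,0,L93F;L210T
Q95G/L210T,PHL7,0,Q95G;L210T
Q95Y/L210T,PHL7,0,Q95Y;L210T
L210T/Q175E,PHL7,0,Q175E;L210T
L93F/Q95G/L210T,PHL7,0,L93F;Q95G;L210T
L93F/Q95Y/L210T,PHL7,0,L93F;Q95Y;L210T
Q95G/L210T/D233K,PHL7,0,Q95G;L210T;D233K
L210T/Q175E/D233K,PHL7,0,Q175E;L210T;D233K
L93F/Q95G/L210T/D233K,PHL7,0,L93F;Q95G;L210T;D233K
L93F/Q95Y/Q175E/D233K,PHL7,0,L93F;Q95Y;Q175E;D233K
L93F/Q95G/L210T/Q175E/D233K,PHL7,0,L93F;Q95G;Q175E;L210T;D233K
R1M1,PHL7,1,Q104L;R111T;T145P;E148K;G155P;T167V;L235T;F248P
R2M1,R1M1,2,E68S;Q104L;H109Y;R111T;N113D;T145P;E148K;G155P;T167V;L176N;S186A;D196S;T219I;L235T;F248P
R2M2,R2M1,2,E6Q;Q34D;D36S;E68S;T91S;Q104L;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;G155P;N161D;T167V;V171I;S186A;D196S;D198P;S208D;D216N;L235T;F248P
R3M1,R2M2,3,E6Q;Q34D;D36S;T91S;Q104L;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;G155P;N161D;T167V;V171I;S186A;D196S;D198P;S208D;D216N;L235T;F248P
R3M2,R2M2,3,E6Q;Q34D;D36S;E68S;T91S;Q104L;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;N161D;T167V;V171I;S186A;D196S;D198P;S208D;D216N;L235T;F248P
R3M3,R2M2,3,E6Q;Q34D;D36S;E68S;T91S;Q104L;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;G155P;N161D;T167V;S186A;D196S;D198P;S208D;D216N;L235T;F248P
R3M4,R2M2,3,E6Q;Q34D;D36S;E68S;T91S;Q104L;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;G155P;N161D;T167V;V171I;D196S;D198P;S208D;D216N;L235T;F248P
R3M5,R2M2,3,E6Q;Q34D;D36S;E68S;T91S;Q104L;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;G155P;N161D;T167V;V171I;S186A;D196S;D198P;D216N;L235T;F248P
R3M6,R2M2,3,E6Q;Q34D;D36S;E68S;T91S;Q104L;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;N161D;T167V;V171I;D196S;D198P;S208D;D216N;L235T;F248P
R3M7,R2M2,3,E6Q;Q34D;D36S;E68S;T91S;Q104L;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;N161D;T167V;V171I;S186A;D196S;D198P;D216N;L235T;F248P
R3M8,R2M2,3,E6Q;Q34D;D36S;E68S;T91S;Q104L;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;G155P;N161D;T167V;V171I;D196S;D198P;D216N;L235T;F248P
R3M9,R2M2,3,E6Q;Q34D;D36S;E68S;T91S;Q104L;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;N161D;T167V;V171I;D196S;D198P;D216N;L235T;F248P
R4M6,R3M9,4,E6Q;Q34D;D36S;E68S;T91S;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;N161D;T167V;V171I;Q175E;D196S;D198P;L210T;D216N;L235T;F248P
R4M9,R4M6,4,E6Q;Q34D;D36S;E68S;T91S;L93F;Q95G;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;N161D;T167V;V171I;Q175E;D196S;D198P;L210T;D216N;L235T;F248P
R4M10,R4M6,4,E6Q;Q34D;D36S;E68S;T91S;L93F;Q95Y;H109Y;R111T;N113D;V115T;N118D;T145P;E148K;N161D;T167V;V171I;Q175E;D196S;D198P;L210T;D216N;L235T;F248P
R4M12,R4M6,4,E6Q;Q34D;D36S;E68S;T91S;H109Y;R111T;N113D;V115T;N118D;T145P;N161D;T167V;V171I;Q175E;D196S;D198P;L210T;D216N;D233K;L235T;F248P
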