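Adams
Baker
Bennett
Brooks
Brown
Carter
Clark
Collins
Cooper
Davis
Edwards
Evans
Fisher
Foster
Garcia
Gray
Green
Hall
Harris
Hayes
Hill
Hughes
Jackson
Johnson
Jones
Kelly
King
Lewis
Lopez
Martin
Mason
Miller
Mitchell
Moore
Morgan
Morris
Murphy
Nelson
Parker
Perez
Phillips
Powell
Price
Reed
Reyes
Richardson
Roberts
Robinson
Rogers
Ross
Russell
Sanchez
Scott
Smith
Stewart
Taylor
Turner
Walker
Ward
Watson
White
Wilson
Wood
Wright
Young
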